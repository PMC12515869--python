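"""Protein-abundance-corrected site quantification.

Raw label-free intensities are made comparable in three multiplicative
steps: per-sample median normalization, per-feature centering to a row
mean of 1 (relative quantification), and division of each modification
site's relative value by its parent protein's, which cancels protein
expression and leaves modification stoichiometry.  Missing values are
propagated, never imputed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import GroupDesign, validate_intensity_table

logger = logging.getLogger(__name__)


def sample_scale_factors(table: pd.DataFrame) -> pd.Series:
    """Per-sample multiplicative factors equalizing column medians.

    Factor_j = median-of-medians / median_j (over present values); a column
    with no present values is an error.
    """
    validate_intensity_table(table)
    medians = table.median(axis=0, skipna=True)
    if medians.isna().any():
        empty = medians.index[medians.isna()].tolist()
        raise ValueError(f"samples with no present values: {empty}")
    target = float(medians.median())
    return target / medians


def normalize_samples(table: pd.DataFrame,
                      factors: pd.Series | None = None) -> pd.DataFrame:
    """Rescale each sample so all column medians equal the median-of-medians.

    Multiplicative per-column scaling: robust to heavy tails, preserves
    within-column rank order.  ``factors`` overrides the factors derived
    from the table itself — used to carry the global proteome's loading
    correction onto the modification-site table, whose own medians are not
    a trustworthy loading estimate when modification changes are
    one-directional.
    """
    if factors is None:
        factors = sample_scale_factors(table)
    else:
        validate_intensity_table(table)
        missing = set(table.columns) - set(factors.index)
        if missing:
            raise ValueError(f"no scale factor for samples: {sorted(missing)}")
    return table.mul(factors, axis=1)


def center_features(table: pd.DataFrame) -> pd.DataFrame:
    """Divide each feature row by the mean of its present values.

    The result is a relative-quantification table whose row means (over
    present values) are 1.
    """
    validate_intensity_table(table)
    means = table.mean(axis=1, skipna=True)
    if means.isna().any():
        empty = means.index[means.isna()].tolist()
        raise ValueError(f"features with no present values: {empty}")
    return table.div(means, axis=0)


def correct_site_by_protein(site_rel: pd.DataFrame, prot_rel: pd.DataFrame,
                            site_map: pd.Series) -> pd.DataFrame:
    """Divide each site's relative quantification by its parent protein's.

    Cancels protein-expression differences so the corrected values track
    modification stoichiometry.  Sites whose parent protein is missing from
    ``prot_rel`` (orphans) are dropped with a logged count; cells where
    either operand is missing stay missing; rows are re-centered to mean 1
    over present values afterwards.
    """
    site_map = pd.Series(site_map)
    unmapped = site_rel.index.difference(site_map.index)
    if len(unmapped):
        raise ValueError(f"sites without protein mapping: {list(unmapped[:5])}")
    parents = site_map.reindex(site_rel.index)
    orphan = ~parents.isin(prot_rel.index)
    if orphan.any():
        logger.warning("dropping %d orphan sites with no quantified parent protein",
                       int(orphan.sum()))
    kept = site_rel.loc[~orphan.to_numpy()]
    parent_vals = prot_rel.loc[parents[~orphan.to_numpy()], kept.columns]
    parent_vals.index = kept.index
    corrected = kept / parent_vals
    return center_features(corrected)


def quantify_pipeline(site_raw: pd.DataFrame, prot_raw: pd.DataFrame,
                      site_map: pd.Series,
                      design: GroupDesign | None = None) -> pd.DataFrame:
    """normalize -> center -> protein-correct, returning the corrected table.

    Both tables are normalized with the per-sample factors derived from the
    protein (global proteome) table; shared factors cancel exactly in the
    site/protein division, so the corrected output carries no
    normalization-induced bias and is invariant to per-sample global scaling
    of the raw inputs.
    """
    if design is not None:
        validate_intensity_table(site_raw, design)
        validate_intensity_table(prot_raw, design)
    factors = sample_scale_factors(prot_raw)
    site_rel = center_features(normalize_samples(site_raw, factors=factors))
    prot_rel = center_features(normalize_samples(prot_raw, factors=factors))
    return correct_site_by_protein(site_rel, prot_rel, site_map)
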