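"""Lactylome catalog summaries.

Sites-per-protein distributions, the single-site protein fraction, flanking
sequence windows around modified lysines, Venn overlap between modification
changes and protein-content changes, and subcellular-compartment tallies.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import pandas as pd

from .core import SiteCatalog

#: padding character used beyond protein termini in flanking windows
PAD = "_"


def sites_per_protein(catalog: SiteCatalog) -> pd.Series:
    """Exact number of modified sites per protein, descending."""
    counts = catalog.frame.groupby("accession").size()
    counts.name = "n_sites"
    return counts.sort_values(ascending=False)


def binned_site_histogram(counts: pd.Series, max_bin: int = 20) -> pd.Series:
    """Histogram of proteins by site count, binned 1, 2, ..., max_bin, >max_bin.

    The histogram total equals the number of modified proteins.
    """
    bins = {str(k): int((counts == k).sum()) for k in range(1, max_bin + 1)}
    bins[f">{max_bin}"] = int((counts > max_bin).sum())
    return pd.Series(bins, name="n_proteins")


def fraction_single_site(catalog: SiteCatalog) -> float:
    """Percent of modified proteins carrying exactly one site, to 2 decimals."""
    if len(catalog) == 0:
        raise ValueError("empty site catalog")
    counts = sites_per_protein(catalog)
    return round(100.0 * float((counts == 1).sum()) / float(len(counts)), 2)


def top_modified_proteins(catalog: SiteCatalog, k: int) -> list[tuple[str, int]]:
    """Top-k proteins by site count; ties broken lexicographically by accession."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = sites_per_protein(catalog)
    ranked = sorted(counts.items(), key=lambda item: (-item[1], item[0]))
    return [(acc, int(n)) for acc, n in ranked[:k]]


def overlap_changed(kla_changed: set[str], content_changed: set[str]) -> tuple[int, int, float]:
    """Venn arithmetic between modification-changed and content-changed proteins.

    Returns ``(n_overlap, n_kla_only, percent_kla_only)`` where the percent is
    100 * n_kla_only / |kla_changed| rounded to 2 decimals (0.0 for an empty
    kla set).
    """
    kla = set(kla_changed)
    content = set(content_changed)
    n_overlap = len(kla & content)
    n_kla_only = len(kla - content)
    pct = round(100.0 * n_kla_only / len(kla), 2) if kla else 0.0
    return n_overlap, n_kla_only, pct


def extract_flank(sequences: Mapping[str, str], accession: str, position: int,
                  w: int = 10) -> str:
    """Window of 2w+1 residues centred on the lysine at ``position`` (1-based).

    Positions beyond the protein termini are padded with '_'.
    """
    try:
        seq = sequences[accession]
    except KeyError:
        raise ValueError(f"unknown accession {accession!r}") from None
    if not 1 <= position <= len(seq):
        raise ValueError(f"position {position} out of range for {accession} "
                         f"(length {len(seq)})")
    if seq[position - 1] != "K":
        raise ValueError(f"residue at {accession}:{position} is "
                         f"{seq[position - 1]!r}, not K")
    idx = position - 1
    left = seq[max(0, idx - w):idx].rjust(w, PAD)
    right = seq[idx + 1:idx + 1 + w].ljust(w, PAD)
    return left + "K" + right


def tally_compartments(proteins: Iterable[str],
                       annotation: Mapping[str, Iterable[str]],
                       sites: SiteCatalog | None = None) -> pd.DataFrame:
    """Per-compartment counts of proteins and (optionally) their sites.

    A protein annotated to several compartments contributes to each of them;
    proteins without annotation fall into an ``unannotated`` bucket.  Returns
    a DataFrame indexed by compartment with columns ``n_proteins`` and
    ``n_sites`` (0 when no catalog given), sorted by descending protein count
    then name.
    """
    proteins = sorted(set(proteins))
    site_counts = (sites_per_protein(sites) if sites is not None and len(sites)
                   else pd.Series(dtype=int))
    prot_tally: dict[str, int] = {}
    site_tally: dict[str, int] = {}
    for acc in proteins:
        labels = list(annotation.get(acc, [])) or ["unannotated"]
        n_sites = int(site_counts.get(acc, 0))
        for label in labels:
            prot_tally[label] = prot_tally.get(label, 0) + 1
            site_tally[label] = site_tally.get(label, 0) + n_sites
    out = pd.DataFrame({
        "n_proteins": pd.Series(prot_tally, dtype=int),
        "n_sites": pd.Series(site_tally, dtype=int),
    })
    if out.empty:
        return pd.DataFrame(columns=["n_proteins", "n_sites"])
    # descending protein count, ties alphabetical (stable sort keeps index order)
    return out.sort_index().sort_values("n_proteins", ascending=False,
                                        kind="mergesort")
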