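"""Two-group differential modification testing.

For each feature of a protein-corrected relative-quantification table the
fold change is the ratio of group means on the linear scale; inference runs
on log2 values through an assumption gate: Shapiro-Wilk normality per group
and Brown-Forsythe (median-centred Levene) variance homogeneity choose
between Student's and Welch's t-test.  P-values are Benjamini-Hochberg
adjusted and calls use the fold-change window (default >1.5 / <1/1.5) with
raw p < alpha, q reported alongside.

The stage is exposed statsmodels-style: :class:`DifferentialModel` holds the
data and thresholds, ``fit()`` returns a :class:`DifferentialResults` with
the per-feature table, summary counts and a volcano plot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import CASE, CONTROL, GroupDesign

STUDENT = "student"
WELCH = "welch"
UNTESTABLE = "untestable"

UP = "up"
DOWN = "down"
NS = "ns"


@dataclass(frozen=True)
class TestGateReport:
    """Outcome of the normality / equal-variance gate for one feature."""

    feature_id: str
    shapiro_p_control: float
    shapiro_p_case: float
    levene_p: float
    decision: str  # student | welch | untestable


def _shapiro_p(values: np.ndarray) -> float:
    """Shapiro-Wilk p; degenerate inputs (n < 3 or zero range) cannot reject
    normality and return 1."""
    if values.size < 3 or np.ptp(values) == 0:
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.shapiro(values).pvalue)


def select_test(control: np.ndarray, case: np.ndarray,
                gate_alpha: float = 0.05,
                feature_id: str = "") -> TestGateReport:
    """Choose Student vs Welch from Shapiro-Wilk and Brown-Forsythe gates.

    ``control`` / ``case`` are log2 relative quantifications with missing
    values already removed.  Student's test is used iff both groups pass
    normality and the variances pass homogeneity at ``gate_alpha``; two
    exactly-constant groups are untestable.
    """
    control = np.asarray(control, dtype=float)
    case = np.asarray(case, dtype=float)
    if control.size < 2 or case.size < 2:
        return TestGateReport(feature_id, np.nan, np.nan, np.nan, UNTESTABLE)
    if np.ptp(control) == 0 and np.ptp(case) == 0:
        return TestGateReport(feature_id, 1.0, 1.0, 1.0, UNTESTABLE)
    sw_ctrl = _shapiro_p(control)
    sw_case = _shapiro_p(case)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lev_p = float(stats.levene(control, case, center="median").pvalue)
    if np.isnan(lev_p):  # identical spreads can yield a 0/0 statistic
        lev_p = 1.0
    decision = (STUDENT if sw_ctrl >= gate_alpha and sw_case >= gate_alpha
                and lev_p >= gate_alpha else WELCH)
    return TestGateReport(feature_id, sw_ctrl, sw_case, lev_p, decision)


def test_feature(control: np.ndarray, case: np.ndarray, decision: str) -> float:
    """Two-sided p from the gated t-test on log2 values (1 if untestable)."""
    if decision == UNTESTABLE:
        return 1.0
    equal_var = decision == STUDENT
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.ttest_ind(case, control, equal_var=equal_var).pvalue)
    return 1.0 if np.isnan(p) else p


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, clipped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compute_fold_change(corrected: pd.DataFrame, design: GroupDesign,
                        min_per_group: int = 2) -> pd.DataFrame:
    """Per-feature case/control ratio of means of present linear values.

    Features with fewer than ``min_per_group`` present values in either
    group are flagged ``testable=False`` (fold change still reported when
    both group means exist).
    """
    ctrl = corrected[list(design.control)]
    case = corrected[list(design.case)]
    n_ctrl = ctrl.notna().sum(axis=1)
    n_case = case.notna().sum(axis=1)
    fc = case.mean(axis=1, skipna=True) / ctrl.mean(axis=1, skipna=True)
    return pd.DataFrame({
        "fc": fc,
        "n_control": n_ctrl,
        "n_case": n_case,
        "testable": (n_ctrl >= min_per_group) & (n_case >= min_per_group),
    })


def call_significant(fc: float, p: float, up_threshold: float = 1.5,
                     down_threshold: float = 1 / 1.5,
                     alpha: float = 0.05) -> str:
    """up / down / ns from the fold-change window and raw p-value."""
    if not fc > 0:
        raise ValueError("fold change must be positive")
    if p < alpha and fc > up_threshold:
        return UP
    if p < alpha and fc < down_threshold:
        return DOWN
    return NS


class DifferentialModel:
    """Gated two-group differential model over a relative-quantification table.

    Parameters
    ----------
    corrected
        Feature x sample table of (protein-corrected) relative
        quantifications; NaN = missing.
    design
        Control/case sample assignment.
    up_threshold, down_threshold, alpha
        Call window: up if fc > up_threshold, down if fc < down_threshold,
        each additionally requiring raw p < alpha.  ``down_threshold`` of
        None means the reciprocal of ``up_threshold``.
    gate_alpha
        Level of the Shapiro-Wilk / Brown-Forsythe assumption gate.
    min_per_group
        Minimum present values per group for a feature to be testable.
    """

    def __init__(self, corrected: pd.DataFrame, design: GroupDesign, *,
                 up_threshold: float = 1.5, down_threshold: float | None = None,
                 alpha: float = 0.05, gate_alpha: float = 0.05,
                 min_per_group: int = 2,
                 feature_map: pd.Series | None = None) -> None:
        self.corrected = corrected
        self.design = design
        self.up_threshold = float(up_threshold)
        self.down_threshold = (1.0 / self.up_threshold if down_threshold is None
                               else float(down_threshold))
        self.alpha = float(alpha)
        self.gate_alpha = float(gate_alpha)
        self.min_per_group = int(min_per_group)
        self.feature_map = feature_map  # optional site -> protein map for counts

    @classmethod
    def from_raw_tables(cls, site_raw: pd.DataFrame, prot_raw: pd.DataFrame,
                        site_map: pd.Series, design: GroupDesign,
                        **kwargs) -> "DifferentialModel":
        """Build from raw site/protein intensities via the quantify chain."""
        from .quantify import quantify_pipeline
        corrected = quantify_pipeline(site_raw, prot_raw, site_map, design)
        kwargs.setdefault("feature_map", pd.Series(site_map))
        return cls(corrected, design, **kwargs)

    def fit(self) -> "DifferentialResults":
        rows = []
        gates = []
        log2_table = np.log2(self.corrected)
        for fid in self.corrected.index:
            ctrl = log2_table.loc[fid, list(self.design.control)].dropna().to_numpy()
            case = log2_table.loc[fid, list(self.design.case)].dropna().to_numpy()
            lin_ctrl = self.corrected.loc[fid, list(self.design.control)].dropna()
            lin_case = self.corrected.loc[fid, list(self.design.case)].dropna()
            fc = (float(lin_case.mean() / lin_ctrl.mean())
                  if len(lin_ctrl) and len(lin_case) else np.nan)
            testable = (len(ctrl) >= self.min_per_group
                        and len(case) >= self.min_per_group)
            if not testable:
                gate = TestGateReport(fid, np.nan, np.nan, np.nan, UNTESTABLE)
            else:
                gate = select_test(ctrl, case, self.gate_alpha, feature_id=fid)
            p = test_feature(ctrl, case, gate.decision)
            gates.append(gate)
            rows.append({"feature_id": fid, "fc": fc,
                         "log2fc": np.log2(fc) if fc and fc > 0 else np.nan,
                         "p": p, "test_used": gate.decision})
        table = pd.DataFrame(rows).set_index("feature_id")
        table["q"] = adjust_bh(table["p"].to_numpy()) if len(table) else []
        calls = []
        for fid, row in table.iterrows():
            if row["test_used"] == UNTESTABLE or not row["fc"] > 0:
                calls.append(NS)
            else:
                calls.append(call_significant(
                    row["fc"], row["p"], self.up_threshold,
                    self.down_threshold, self.alpha))
        table["call"] = calls
        table = table[["fc", "log2fc", "p", "q", "test_used", "call"]]
        return DifferentialResults(self, table, gates)


class DifferentialResults:
    """Per-feature estimates, calls and diagnostics from a fitted model."""

    def __init__(self, model: DifferentialModel, table: pd.DataFrame,
                 gate_reports: list[TestGateReport]) -> None:
        self.model = model
        self.table = table
        self.gate_reports = gate_reports

    @property
    def counts(self) -> dict[str, int]:
        t = self.table
        untestable = int((t["test_used"] == UNTESTABLE).sum())
        return {
            "n_features": len(t),
            "up": int((t["call"] == UP).sum()),
            "down": int((t["call"] == DOWN).sum()),
            "ns": int(((t["call"] == NS) & (t["test_used"] != UNTESTABLE)).sum()),
            "untestable": untestable,
        }

    def changed_features(self, direction: str | None = None) -> list[str]:
        t = self.table
        if direction is None:
            mask = t["call"].isin([UP, DOWN])
        else:
            mask = t["call"] == direction
        return t.index[mask].tolist()

    def changed_proteins(self, direction: str | None = None) -> set[str]:
        """Distinct parent proteins of changed features (needs feature_map)."""
        feats = self.changed_features(direction)
        fmap = self.model.feature_map
        if fmap is None:
            return set(feats)
        return set(pd.Series(fmap).reindex(feats).dropna())

    def volcano_frame(self) -> pd.DataFrame:
        """log2fc vs -log10 p table for volcano plotting."""
        out = self.table[["log2fc", "p", "call"]].copy()
        out["neg_log10_p"] = -np.log10(np.clip(out["p"], 1e-300, None))
        return out[["log2fc", "neg_log10_p", "call"]]

    def plot_volcano(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        frame = self.volcano_frame().dropna()
        colors = {UP: "#c23b22", DOWN: "#2c64a8", NS: "#9a9a9a"}
        for call, sub in frame.groupby("call"):
            ax.scatter(sub["log2fc"], sub["neg_log10_p"], s=8,
                       c=colors.get(call, "#9a9a9a"), label=call, alpha=0.7)
        ax.axhline(-np.log10(self.model.alpha), ls="--", lw=0.8, c="k")
        for thr in (self.model.up_threshold, self.model.down_threshold):
            ax.axvline(np.log2(thr), ls="--", lw=0.8, c="k")
        ax.set_xlabel("log2 fold change (case / control)")
        ax.set_ylabel("-log10 p")
        ax.legend(frameon=False, fontsize=8)
        return ax

    def summary(self) -> str:
        c = self.counts
        m = self.model
        lines = [
            "Two-group differential modification analysis",
            "============================================",
            f"features: {c['n_features']}  (untestable: {c['untestable']})",
            f"groups:   {len(m.design.control)} control vs {len(m.design.case)} case",
            f"call window: fc > {m.up_threshold:g} or fc < {m.down_threshold:.4g}, "
            f"p < {m.alpha:g} (gate alpha {m.gate_alpha:g})",
            f"up:   {c['up']}",
            f"down: {c['down']}",
            f"ns:   {c['ns']}",
        ]
        tests = self.table["test_used"].value_counts()
        lines.append("tests used: " + ", ".join(
            f"{name}={int(n)}" for name, n in tests.items()))
        return "\n".join(lines)


def run_differential(corrected: pd.DataFrame, design: GroupDesign,
                     **kwargs) -> DifferentialResults:
    """Convenience wrapper: fit a :class:`DifferentialModel` in one call."""
    return DifferentialModel(corrected, design, **kwargs).fit()
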