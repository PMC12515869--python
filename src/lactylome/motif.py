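"""Positional amino-acid frequency and motif enrichment around modified lysines.

Foreground windows are the 2w+1-residue flanks of modified sites; the
background is every lysine-centred window of the proteome (the motif-x
convention of matching the central residue).  Per-cell enrichment uses the
exact binomial tail of the foreground count at the background frequency;
the iterative motif search greedily fixes the most over-represented
(position, residue) cell, restricts both window sets to matches, and
recurses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import PAD
from .simulate import AMINO_ACIDS

RESIDUES = list(AMINO_ACIDS)


def window_offsets(w: int) -> list[int]:
    """Flank offsets -w..-1, +1..+w (the centre lysine is excluded)."""
    return [o for o in range(-w, w + 1) if o != 0]


@dataclass
class PositionFrequencyMatrix:
    """Residue x position counts over a set of K-centred windows.

    ``counts`` rows are the 20 residues plus the '_' padding bucket, columns
    the flank offsets; every column sums to ``n_windows``.
    """

    counts: pd.DataFrame
    n_windows: int

    @property
    def w(self) -> int:
        return max(self.counts.columns)

    def frequencies(self) -> pd.DataFrame:
        """Per-position frequencies over residues + padding (columns sum to 1)."""
        return self.counts / self.n_windows

    def residue_counts(self) -> pd.DataFrame:
        return self.counts.loc[RESIDUES]

    def present_per_position(self) -> pd.Series:
        """Number of windows with a real (non-padding) residue per position."""
        return self.counts.loc[RESIDUES].sum(axis=0)


def _check_windows(windows: list[str], w: int) -> None:
    width = 2 * w + 1
    for win in windows:
        if len(win) != width:
            raise ValueError(f"window {win!r} has length {len(win)}, expected {width}")
        if win[w] != "K":
            raise ValueError(f"window {win!r} is not centred on K")
        bad = set(win) - set(AMINO_ACIDS) - {PAD}
        if bad:
            raise ValueError(f"window {win!r} has invalid characters {sorted(bad)}")


def position_frequency_matrix(windows: list[str], w: int) -> PositionFrequencyMatrix:
    """Exact positional residue counts for K-centred windows of width 2w+1."""
    _check_windows(windows, w)
    offsets = window_offsets(w)
    counts = pd.DataFrame(0, index=RESIDUES + [PAD], columns=offsets, dtype=int)
    for win in windows:
        for off in offsets:
            counts.loc[win[w + off], off] += 1
    return PositionFrequencyMatrix(counts=counts, n_windows=len(windows))


def positional_enrichment(fg: PositionFrequencyMatrix,
                          bg: PositionFrequencyMatrix) -> pd.DataFrame:
    """Per (position, residue) log2 enrichment of foreground over background.

    Frequencies are computed among non-padding residues at each position; a
    pseudo-frequency of 0.5/n is added to both sides of the ratio so empty
    background cells stay finite (flagged in ``bg_zero``), while the exact
    binomial tail p uses raw counts.
    """
    if fg.w != bg.w:
        raise ValueError("foreground and background widths differ")
    fg_n = fg.present_per_position()
    bg_n = bg.present_per_position()
    rows = []
    for off in window_offsets(fg.w):
        n_fg = int(fg_n[off])
        n_bg = int(bg_n[off])
        for res in RESIDUES:
            k = int(fg.counts.loc[res, off])
            k_bg = int(bg.counts.loc[res, off])
            bg_freq = k_bg / n_bg if n_bg else 0.0
            fg_pseudo = (k + 0.5 / max(n_fg, 1)) / max(n_fg, 1) if n_fg else 0.0
            bg_pseudo = ((k_bg + 0.5 / max(n_bg, 1)) / max(n_bg, 1)) if n_bg else 0.0
            ratio = fg_pseudo / bg_pseudo if bg_pseudo > 0 else np.nan
            p_freq = bg_freq if (bg_freq > 0 or k == 0) else 0.5 / n_bg
            p = float(stats.binom.sf(k - 1, n_fg, p_freq)) if n_fg else 1.0
            rows.append({"position": off, "residue": res, "fg_count": k,
                         "fg_n": n_fg, "bg_count": k_bg, "bg_n": n_bg,
                         "fg_freq": k / n_fg if n_fg else np.nan,
                         "bg_freq": bg_freq,
                         "log2_ratio": np.log2(ratio) if ratio and ratio > 0 else np.nan,
                         "p": p, "bg_zero": bool(n_bg and k_bg == 0 and k > 0)})
    return pd.DataFrame(rows)


@dataclass
class MotifResult:
    """A fixed-residue motif found by the iterative search."""

    pattern: dict[int, str]  # offset -> residue
    fg_matches: int
    bg_matches: int
    fold_enrichment: float
    p: float

    def pattern_string(self, w: int) -> str:
        """Human-readable motif, e.g. 'A.K..E' style with the centre K."""
        chars = []
        for off in range(-w, w + 1):
            if off == 0:
                chars.append("K")
            else:
                chars.append(self.pattern.get(off, "."))
        return "".join(chars).strip(".") or "K"


def _matches(window: str, w: int, pattern: dict[int, str]) -> bool:
    # padding never matches a fixed motif position
    return all(window[w + off] == res for off, res in pattern.items())


def _best_cell(fg: list[str], bg: list[str], w: int,
               fixed: dict[int, str]) -> tuple[int, str, int, float] | None:
    """Cell (offset, residue) with the smallest binomial p among unfixed
    positions; ties broken by (offset, residue).  Returns
    (offset, residue, fg_count, p) or None when no countable cell exists."""
    n_fg = len(fg)
    n_bg = len(bg)
    if n_fg == 0 or n_bg == 0:
        return None
    best: tuple[float, int, str, int] | None = None
    for off in window_offsets(w):
        if off in fixed:
            continue
        fg_col = [win[w + off] for win in fg]
        bg_col = [win[w + off] for win in bg]
        for res in RESIDUES:
            k = fg_col.count(res)
            if k == 0:
                continue
            bg_k = bg_col.count(res)
            bg_freq = bg_k / n_bg if bg_k else 0.5 / n_bg
            p = float(stats.binom.sf(k - 1, n_fg, bg_freq))
            key = (p, off, res, k)
            if best is None or key[:3] < best[:3]:
                best = key
    if best is None:
        return None
    p, off, res, k = best
    return off, res, k, p


def motif_x_search(fg_windows: list[str], bg_windows: list[str], w: int = 10,
                   p_threshold: float = 1e-6, min_occurrences: int = 20,
                   max_depth: int = 5) -> list[MotifResult]:
    """Greedy iterative motif extraction (motif-x style).

    Repeatedly grows a motif by fixing the (position, residue) cell with the
    smallest binomial tail p, provided p < ``p_threshold`` and the cell is
    supported by at least ``min_occurrences`` foreground windows; both window
    sets are then restricted to matches and the growth recurses up to
    ``max_depth`` fixed positions.  A completed motif removes its foreground
    and background matches and the search restarts.  Deterministic given its
    inputs (ties break lexicographically).
    """
    _check_windows(fg_windows, w)
    _check_windows(bg_windows, w)
    fg_pool = list(fg_windows)
    bg_pool = list(bg_windows)
    n_bg_total = len(bg_pool)
    results: list[MotifResult] = []
    while len(fg_pool) >= min_occurrences and bg_pool:
        fg_cur = fg_pool
        bg_cur = bg_pool
        fixed: dict[int, str] = {}
        motif_p = 1.0
        while len(fixed) < max_depth:
            cell = _best_cell(fg_cur, bg_cur, w, fixed)
            if cell is None:
                break
            off, res, k, p = cell
            if p >= p_threshold or k < min_occurrences:
                break
            fixed[off] = res
            motif_p = p
            fg_cur = [win for win in fg_cur if win[w + off] == res]
            bg_cur = [win for win in bg_cur if win[w + off] == res]
        if not fixed:
            break
        fg_frac = len(fg_cur) / len(fg_pool)
        bg_frac = max(len(bg_cur), 0.5) / max(len(bg_pool), 1)
        results.append(MotifResult(
            pattern=dict(sorted(fixed.items())),
            fg_matches=len(fg_cur), bg_matches=len(bg_cur),
            fold_enrichment=fg_frac / bg_frac, p=motif_p))
        fg_pool = [win for win in fg_pool if not _matches(win, w, fixed)]
        bg_pool = [win for win in bg_pool if not _matches(win, w, fixed)]
        if n_bg_total and not bg_pool:
            break
    return results


def proteome_background_windows(sequences: dict[str, str], w: int = 10) -> list[str]:
    """All K-centred 2w+1 windows of a proteome ('_'-padded at termini)."""
    from .catalog import extract_flank

    windows = []
    for acc, seq in sequences.items():
        for i, aa in enumerate(seq):
            if aa == "K":
                windows.append(extract_flank(sequences, acc, i + 1, w=w))
    return windows
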