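"""Demonstration statistics: landscape ranking, nucleotide ANOVA and
functional-segment correlation summaries."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scan import WindowRecord
from .usage import GenusUsageDB

NUCLEOTIDES = "ACGT"


def landscape(
    window: WindowRecord,
    genus_dbs: Sequence[GenusUsageDB],
    measure: str = "bias",
) -> pd.DataFrame:
    """Rank all genera by a window's usage value, descending.

    `measure` is ``"bias"`` (trimer usage bias) or ``"codon9"`` (3-codon
    usage alone).  Ties keep genus input order (stable sort); ranks are
    1..I.  The returned frame carries the maximum and its genus in
    ``attrs``.
    """
    if measure == "bias":
        values = [db.bias(window.aa_trimer, window.nine_mer) for db in genus_dbs]
    elif measure == "codon9":
        values = [
            db.codon9_usage.get(window.aa_trimer, {}).get(window.nine_mer, 0.0)
            for db in genus_dbs
        ]
    else:
        raise ValueError(f"unknown measure {measure!r}")
    order = np.argsort(-np.asarray(values), kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    df = pd.DataFrame(
        {
            "genus": [db.genus_id for db in genus_dbs],
            "value": values,
            "rank": ranks,
        }
    )
    df.attrs["window"] = window.abbrev_long
    df.attrs["measure"] = measure
    df.attrs["max_value"] = float(values[order[0]]) if len(values) else float("nan")
    df.attrs["max_genus"] = genus_dbs[order[0]].genus_id if len(values) else None
    return df


def _one_way_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Textbook fixed-effects one-way ANOVA on raw group samples.

    Zero within-group variance with equal means gives F = 0; zero within-
    group variance with unequal means gives F = inf, p -> 0.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    k = len(groups)
    n = sum(len(g) for g in groups)
    if k < 2:
        raise ValueError("ANOVA needs at least 2 non-empty groups")
    if n - k < 1:
        raise ValueError(f"degenerate degrees of freedom: n={n}, k={k}")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between, df_within = k - 1, n - k
    if ss_within == 0:
        if np.isclose(ss_between, 0.0):
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(F, df_between, df_within))
    return float(F), p


def nucleotide_anova(
    windows: Sequence[WindowRecord] | Sequence[str],
    assignments: Sequence[int],
) -> pd.DataFrame:
    """One-way ANOVA of per-9-mer nucleotide counts among loading clusters.

    For each nucleotide A/C/G/T, every window contributes its raw count
    (0-9) in the 9-mer, grouped by cluster assignment; F compares the
    cluster means.  Returns a frame indexed by nucleotide with columns
    ``F`` and ``p``.
    """
    mers = [w.nine_mer if isinstance(w, WindowRecord) else str(w) for w in windows]
    if len(mers) != len(assignments):
        raise ValueError("windows and assignments differ in length")
    labels = np.asarray(assignments)
    rows = {}
    for nt in NUCLEOTIDES:
        counts = np.array([m.count(nt) for m in mers], dtype=float)
        groups = [counts[labels == c] for c in np.unique(labels)]
        rows[nt] = _one_way_anova(groups)
    return pd.DataFrame(rows, index=["F", "p"]).T


@dataclass
class FSAssignment:
    """Partition of matching windows into functional segments (FSs)."""

    window_to_fs: dict[int, str] = field(default_factory=dict)

    def members(self, fs_label: str) -> list[int]:
        return sorted(i for i, l in self.window_to_fs.items() if l == fs_label)

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.window_to_fs.values():
            seen.setdefault(l, None)
        return list(seen)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FSAssignment":
        """Read ``start<TAB>end<TAB>label`` rows (inclusive window ranges)."""
        fs = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            start, end, label = line.rstrip("\n").split("\t")
            for idx in range(int(start), int(end) + 1):
                if idx in fs.window_to_fs:
                    raise ValueError(f"window {idx} assigned to two segments")
                fs.window_to_fs[idx] = label
        return fs


def fs_correlation(
    usage_matrix: np.ndarray,
    genus_labels: Sequence[str],
    genus_group_map: Mapping[str, str],
) -> pd.DataFrame:
    """Mean genus-genus Pearson correlation per pair of taxonomic groups.

    `usage_matrix` holds one functional segment: windows in rows, genera in
    columns.  Columns are centered, genus-genus correlations (I x I) are
    taken over the window-indexed vectors, and for each unordered group pair
    (same-group pairs included) the mean over all qualifying genus pairs is
    returned; self-pairs are excluded, so a group with a single genus has an
    undefined (NaN) same-group mean.
    """
    M = np.asarray(usage_matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("functional segment needs at least 2 windows")
    if M.shape[1] != len(genus_labels):
        raise ValueError("matrix columns and genus labels differ in length")
    Mc = M - M.mean(axis=0, keepdims=True)
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(Mc, rowvar=False)
    groups = [genus_group_map[g] for g in genus_labels]
    pair_values: dict[tuple[str, str], list[float]] = {}
    I = len(genus_labels)
    for i in range(I):
        for j in range(i + 1, I):
            key = tuple(sorted((groups[i], groups[j])))
            pair_values.setdefault(key, []).append(R[i, j])
    all_groups = sorted(set(groups))
    records = []
    for a_idx, a in enumerate(all_groups):
        for b in all_groups[a_idx:]:
            vals = pair_values.get((a, b), [])
            records.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_correlation": float(np.mean(vals)) if vals else float("nan"),
                    "n_pairs": len(vals),
                }
            )
    return pd.DataFrame.from_records(records)


def fs_correlation_summary(
    per_fs_means: Mapping[str, pd.DataFrame]
) -> pd.DataFrame:
    """Mean and standard deviation across FSs of each group pair's mean
    correlation (population SD, as a descriptive summary)."""
    frames = []
    for fs_label, df in per_fs_means.items():
        d = df.copy()
        d["fs"] = fs_label
        frames.append(d)
    stacked = pd.concat(frames, ignore_index=True)
    out = (
        stacked.groupby(["group_a", "group_b"])["mean_correlation"]
        .agg(mean="mean", sd=lambda s: float(np.std(s.dropna(), ddof=0)), n_fs="count")
        .reset_index()
    )
    return out
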