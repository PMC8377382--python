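"""K-means clustering of loadings and taxon scores, and outlier flagging.

Loadings are clustered twice (L1: 80% components, default k=13; L2:
first/second components) and so are taxon scores (T1/T2, default k=10).
Windows landing in clusters of size <= 2 are flagged as outliers — the
candidate position-specific functional sites.  Trimer-level catalytic
(CSA) / allosteric (ASD) annotation keys on the second residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .pca import CorrelationPCA

DEFAULT_K_LOADING = 13
DEFAULT_K_GENUS = 10


@dataclass
class ClusterReport:
    """Result of one K-means run, with clusters relabelled by size.

    Cluster ids are relabelled in decreasing size order (ties by first
    occurrence), so cluster 0 is always the largest — deterministic
    reporting regardless of the solver's internal labelling.
    """

    item_kind: str  # "loading-window" | "genus"
    basis: str  # "components-80" | "first-second"
    k: int
    assignments: np.ndarray
    sizes: dict[int, int]
    outlier_flags: np.ndarray | None = None
    seed: int | None = 0
    restarts: int = 10
    iterations: int = 0

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def _relabel_by_size(labels: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    ids, counts = np.unique(labels, return_counts=True)
    first_seen = {c: int(np.flatnonzero(labels == c)[0]) for c in ids}
    order = sorted(ids, key=lambda c: (-counts[list(ids).index(c)], first_seen[c]))
    mapping = {old: new for new, old in enumerate(order)}
    new_labels = np.array([mapping[c] for c in labels])
    sizes = {mapping[c]: int(n) for c, n in zip(ids, counts)}
    return new_labels, sizes


def kmeans(
    points: np.ndarray,
    k: int,
    seed: int | None = 0,
    restarts: int = 10,
    max_iter: int = 100,
    item_kind: str = "loading-window",
    basis: str = "components-80",
) -> ClusterReport:
    """Euclidean K-means, best of `restarts` random initialisations.

    `k` is clamped to [1, number of points]; empty clusters vanish in the
    size-ordered relabelling.  Reproducible given `seed`.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim == 1:
        points = points[:, np.newaxis]
    n = points.shape[0]
    if n < 1:
        raise ValueError("need at least one point")
    k_eff = int(np.clip(k, 1, n))
    km = KMeans(
        n_clusters=k_eff,
        n_init=restarts,
        max_iter=max_iter,
        random_state=seed,
    ).fit(points)
    labels, sizes = _relabel_by_size(km.labels_)
    return ClusterReport(
        item_kind=item_kind,
        basis=basis,
        k=k_eff,
        assignments=labels,
        sizes=sizes,
        seed=seed,
        restarts=restarts,
        iterations=int(km.n_iter_),
    )


def flag_outliers(report: ClusterReport, max_size: int = 2) -> np.ndarray:
    """Flag items in clusters of size <= `max_size`; stores and returns a
    boolean mask aligned with the items."""
    flags = np.array(
        [report.sizes[c] <= max_size for c in report.assignments], dtype=bool
    )
    report.outlier_flags = flags
    return flags


def annotate_subgroup(
    aa_trimer: str, csa_residues: set[str], asd_residues: set[str]
) -> str:
    """Subgroup of a trimer by its second residue: ``CSA``, ``ASD``,
    ``BothCA`` (both) or ``None`` (neither)."""
    second = aa_trimer[1]
    in_csa = second in csa_residues
    in_asd = second in asd_residues
    if in_csa and in_asd:
        return "BothCA"
    if in_csa:
        return "CSA"
    if in_asd:
        return "ASD"
    return "None"


_K_PLAIN = re.compile(r"^(\d+)_(\d+)$")
_K_AUTO = re.compile(r"^auto_(\d+)_(\d+)$")


def auto_k(option_string: str, n_windows: int) -> tuple[int, int]:
    """Parse a k-option string into ``(k_genus, k_loading)``.

    Plain form ``"<kg>_<kl>"`` gives the two integers directly.  Auto form
    ``"auto_<kg>_<divisor>"`` sets the loading k to one `divisor`-th of the
    number of matching windows, clamped to [2, n_windows].
    """
    m = _K_PLAIN.match(option_string)
    if m:
        return int(m.group(1)), int(m.group(2))
    m = _K_AUTO.match(option_string)
    if m:
        kg, divisor = int(m.group(1)), int(m.group(2))
        if divisor == 0:
            raise ValueError("auto divisor must be positive")
        kl = int(np.clip(n_windows // divisor, 2, max(2, n_windows)))
        return kg, kl
    raise ValueError(
        f"malformed k option {option_string!r}: expected '<k_genus>_<k_loading>' "
        "(e.g. 11_15) or 'auto_<k_genus>_<divisor>' (e.g. auto_14_8)"
    )


@dataclass
class TrimerAnnotation:
    """Residue-level CSA/ASD site sets plus trimer-level function strings."""

    csa_residues: set[str] = field(default_factory=set)
    asd_residues: set[str] = field(default_factory=set)
    functions: dict[str, list[str]] = field(default_factory=dict)

    def subgroup(self, aa_trimer: str) -> str:
        return annotate_subgroup(aa_trimer, self.csa_residues, self.asd_residues)

    def functions_of(self, aa_trimer: str) -> list[str]:
        return self.functions.get(aa_trimer, [])

    @classmethod
    def load(
        cls,
        csa_path: str | Path | None = None,
        asd_path: str | Path | None = None,
        functions_path: str | Path | None = None,
    ) -> "TrimerAnnotation":
        """Load from plain TSVs: one residue per line for the site sets;
        ``aa_trimer<TAB>function`` lines for the function table."""

        def read_set(path):
            if path is None:
                return set()
            return {
                line.strip()
                for line in Path(path).read_text().splitlines()
                if line.strip() and not line.startswith("#")
            }

        ann = cls(csa_residues=read_set(csa_path), asd_residues=read_set(asd_path))
        if functions_path is not None:
            for line in Path(functions_path).read_text().splitlines():
                if not line.strip() or line.startswith("#"):
                    continue
                aa, func = line.rstrip("\n").split("\t", 1)
                ann.functions.setdefault(aa, []).append(func)
        return ann


class WindowOutlierDetector(BaseEstimator):
    """End-to-end outlier detector over a comparative bias matrix Z.

    ``fit(Z)`` runs correlation (or covariance) PCA, K-means on the loading
    rows over the 80% components, and flags windows in clusters of size
    <= `outlier_max_size`.  ``fit_predict`` returns the boolean outlier mask
    aligned with the input columns (dropped degenerate columns are never
    flagged).

    Attributes
    ----------
    pca_ : CorrelationPCA
    loading_report_ : ClusterReport
    outlier_mask_ : ndarray of shape (J,)
    """

    def __init__(
        self,
        k: int = DEFAULT_K_LOADING,
        basis: str = "components-80",
        mode: str = "correlation",
        outlier_max_size: int = 2,
        seed: int | None = 0,
        restarts: int = 10,
        max_iter: int = 100,
    ):
        self.k = k
        self.basis = basis
        self.mode = mode
        self.outlier_max_size = outlier_max_size
        self.seed = seed
        self.restarts = restarts
        self.max_iter = max_iter

    def fit(self, Z, y=None):
        Z = np.asarray(Z, dtype=float)
        self.pca_ = CorrelationPCA(mode=self.mode).fit(Z)
        points = (
            self.pca_.loadings_80()
            if self.basis == "components-80"
            else self.pca_.loadings_first_second()
        )
        self.loading_report_ = kmeans(
            points,
            self.k,
            seed=self.seed,
            restarts=self.restarts,
            max_iter=self.max_iter,
            item_kind="loading-window",
            basis=self.basis,
        )
        flags = flag_outliers(self.loading_report_, self.outlier_max_size)
        mask = np.zeros(Z.shape[1], dtype=bool)
        mask[self.pca_.kept_columns_] = flags
        self.outlier_mask_ = mask
        return self

    def fit_predict(self, Z, y=None):
        return self.fit(Z).outlier_mask_
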