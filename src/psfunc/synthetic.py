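"""Synthetic worlds for testing the pipeline without genome downloads.

Two generators are provided.

* A codon-preference world: taxonomic groups get broadly different
  synonymous-codon preference profiles, genera within a group get small
  perturbations of their group's profile, and CDS are sampled codon-by-codon
  — emulating usage signatures that vary widely between taxonomic groups but
  little within one.
* A planted-outlier world: per-genus window *count tables* are constructed
  directly so that the across-genus 3-codon-usage profile of every query
  window is strongly concordant except at planted positions, whose profiles
  are permuted across genera (decorrelated).  Counts flow through the normal
  usage-table computation, so the experiment exercises the real pipeline
  from counts to outlier flags.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .chargroups import STOP
from .codons import SYNONYMOUS_CODONS, translate
from .refdb import TrimerRefDB, build_trimer_ref
from .usage import GenusUsageDB, compute_genus_usage, scan_cds

RESIDUES = sorted(r for r in SYNONYMOUS_CODONS if r != STOP)
#: residues with at least two synonymous codons (all but M and W)
MULTI_CODON_RESIDUES = [r for r in RESIDUES if len(SYNONYMOUS_CODONS[r]) >= 2]


@dataclass
class SyntheticSpec:
    """Stated world for the codon-preference generator.

    Defaults keep tests fast: 12 genera in 4 taxonomic groups, 20 CDS of
    50-150 codons per genus.  ``within_group_scale`` is the log-normal
    perturbation applied to a group's codon weights to derive each genus
    (small, so within-group variation stays low); ``group_concentration``
    is the Dirichlet concentration generating group profiles (below 1, so
    preferences differ broadly between groups).
    """

    n_genera: int = 12
    n_groups: int = 4
    cds_per_genus: int = 20
    cds_length_codons: tuple[int, int] = (50, 150)
    within_group_scale: float = 0.05
    group_concentration: float = 0.5
    seed: int = 0
    #: optional explicit profiles: group index -> {residue: codon weights}
    codon_profiles: dict[int, dict[str, np.ndarray]] | None = None

    def group_of(self, genus: int) -> int:
        return genus % self.n_groups

    @property
    def genus_labels(self) -> list[str]:
        return [f"genus{g:02d}" for g in range(self.n_genera)]

    @property
    def group_map(self) -> dict[str, str]:
        return {
            label: f"group{self.group_of(g)}"
            for g, label in enumerate(self.genus_labels)
        }


def full_panel_spec(seed: int = 0) -> SyntheticSpec:
    """Preset mirroring a full-scale survey panel: 54 genera in 13 groups."""
    return SyntheticSpec(n_genera=54, n_groups=13, seed=seed)


def disjoint_preference_profiles(
    preferred_weight: float = 0.9,
) -> dict[int, dict[str, np.ndarray]]:
    """Two group profiles preferring disjoint synonymous codons.

    Group 0 puts `preferred_weight` on each residue's first codon, group 1
    on its last; single-codon residues are unaffected.
    """
    profiles: dict[int, dict[str, np.ndarray]] = {0: {}, 1: {}}
    for r in RESIDUES:
        n = len(SYNONYMOUS_CODONS[r])
        for group, pref in ((0, 0), (1, n - 1)):
            w = np.full(n, (1 - preferred_weight) / max(1, n - 1))
            w[pref] = preferred_weight if n > 1 else 1.0
            profiles[group][r] = w / w.sum()
    return profiles


def degenerate_profiles(n_groups: int) -> dict[int, dict[str, np.ndarray]]:
    """One-codon-per-residue profiles (first synonymous codon each)."""
    out: dict[int, dict[str, np.ndarray]] = {}
    for g in range(n_groups):
        out[g] = {}
        for r in RESIDUES:
            w = np.zeros(len(SYNONYMOUS_CODONS[r]))
            w[0] = 1.0
            out[g][r] = w
    return out


class SyntheticWorld:
    """Materialised codon-preference world: profiles, CDS, usage DBs."""

    def __init__(self, spec: SyntheticSpec):
        self.spec = spec
        rng = np.random.default_rng([spec.seed, 101])
        if spec.codon_profiles is not None:
            self._group_profiles = spec.codon_profiles
        else:
            self._group_profiles = {
                g: {
                    r: rng.dirichlet(
                        np.full(len(SYNONYMOUS_CODONS[r]), spec.group_concentration)
                    )
                    for r in RESIDUES
                }
                for g in range(spec.n_groups)
            }
        self._genus_profiles = {}
        for genus in range(spec.n_genera):
            grng = np.random.default_rng([spec.seed, 202, genus])
            base = self._group_profiles[spec.group_of(genus)]
            prof = {}
            for r in RESIDUES:
                w = base[r] * np.exp(
                    spec.within_group_scale * grng.standard_normal(len(base[r]))
                )
                prof[r] = w / w.sum()
            self._genus_profiles[genus] = prof

    def genus_profile(self, genus: int) -> dict[str, np.ndarray]:
        return self._genus_profiles[genus]

    def generate_genus_cds(self, genus: int) -> list[SeqRecord]:
        """Sample the genus's CDS set codon-by-codon from its profile."""
        spec = self.spec
        rng = np.random.default_rng([spec.seed, 303, genus])
        prof = self._genus_profiles[genus]
        records = []
        lo, hi = spec.cds_length_codons
        for c in range(spec.cds_per_genus):
            n_codons = int(rng.integers(lo, hi + 1))
            residues = rng.choice(RESIDUES, size=n_codons)
            codons = [
                SYNONYMOUS_CODONS[r][rng.choice(len(prof[r]), p=prof[r])]
                for r in residues
            ]
            records.append(
                SeqRecord(
                    Seq("".join(codons)),
                    id=f"{spec.genus_labels[genus]}_cds{c:03d}",
                    description="",
                )
            )
        return records

    def build_dbs(self) -> tuple[TrimerRefDB, list[GenusUsageDB]]:
        """Scan every genus's CDS and build the reference + usage DBs.

        The reference covers the union of amino-acid trimers observed in any
        genus, expanded to all synonymous 9-mers.
        """
        counts = {
            g: scan_cds(self.generate_genus_cds(g))
            for g in range(self.spec.n_genera)
        }
        trimers = sorted({aa for c in counts.values() for (aa, _) in c})
        ref = build_trimer_ref(trimers, "all_synonymous")
        dbs = [
            compute_genus_usage(self.spec.genus_labels[g], counts[g], ref)
            for g in range(self.spec.n_genera)
        ]
        return ref, dbs


def generate_genus_cds(spec: SyntheticSpec, genus: int) -> list[SeqRecord]:
    """Functional wrapper over :meth:`SyntheticWorld.generate_genus_cds`."""
    return SyntheticWorld(spec).generate_genus_cds(genus)


# ---------------------------------------------------------------------------
# planted-outlier worlds


@dataclass
class PlantedWorld:
    """A query plus usage DBs with known outlier positions."""

    query: str
    truth: np.ndarray  # boolean, one flag per frame-1 window
    ref: TrimerRefDB
    genus_dbs: list[GenusUsageDB]
    genus_labels: list[str] = field(default_factory=list)


def _sample_query_codons(n_codons: int, rng: np.random.Generator) -> list[str]:
    """Codons whose residues all have >= 2 synonymous codons, with all
    3-codon windows carrying distinct amino-acid trimers."""
    for _ in range(200):
        residues = rng.choice(MULTI_CODON_RESIDUES, size=n_codons)
        trimers = ["".join(residues[j : j + 3]) for j in range(n_codons - 2)]
        if len(set(trimers)) == len(trimers):
            codons = [SYNONYMOUS_CODONS[r][0] for r in residues]
            return codons
    raise RuntimeError("could not sample a repeat-free query")


def plant_outlier_query(
    n_genera: int = 12,
    n_windows: int = 30,
    outlier_positions: Sequence[int] = (),
    strength: float = 1.0,
    seed: int = 0,
    counts_per_trimer: int = 100_000,
    noise_sd: float = 0.03,
) -> PlantedWorld:
    """Construct a query and genus DBs with decorrelated planted windows.

    Non-outlier windows share one across-genus usage profile (an evenly
    spread genus baseline plus small noise), so their Z columns are strongly
    mutually correlated.  At each planted position the baseline is permuted
    across genera and mixed in with weight `strength` (0 = no effect,
    1 = fully permuted), decorrelating that column.  Truth labels are
    returned for recovery scoring.
    """
    if any(p >= n_windows or p < 0 for p in outlier_positions):
        raise ValueError("outlier positions must lie in [0, n_windows)")
    rng = np.random.default_rng([seed, 404])
    codons = _sample_query_codons(n_windows + 2, rng)
    query = "".join(codons)

    mer_of = [query[3 * j : 3 * j + 9] for j in range(n_windows)]
    trimer_of = [translate(m) for m in mer_of]

    baseline = np.linspace(0.15, 0.85, n_genera)
    perm = rng.permutation(n_genera)
    while np.all(perm == np.arange(n_genera)):
        perm = rng.permutation(n_genera)

    ref = build_trimer_ref(trimer_of, "all_synonymous")
    genus_labels = [f"genus{i:02d}" for i in range(n_genera)]
    dbs = []
    outliers = set(outlier_positions)
    for i in range(n_genera):
        counts: Counter = Counter()
        for j in range(n_windows):
            base = baseline[perm[i]] if j in outliers else baseline[i]
            v = (1 - strength) * baseline[i] + strength * base if j in outliers else base
            v = float(np.clip(v + rng.normal(0.0, noise_sd), 0.02, 0.98))
            n_obs = int(round(v * counts_per_trimer))
            alt = next(
                m for m in sorted(ref.nine_mers(trimer_of[j])) if m != mer_of[j]
            )
            counts[(trimer_of[j], mer_of[j])] = n_obs
            counts[(trimer_of[j], alt)] = counts_per_trimer - n_obs
        dbs.append(compute_genus_usage(genus_labels[i], counts, ref))

    truth = np.zeros(n_windows, dtype=bool)
    truth[list(outliers)] = True
    return PlantedWorld(
        query=query, truth=truth, ref=ref, genus_dbs=dbs, genus_labels=genus_labels
    )


def recovery_rate(
    n_seeds: int = 20,
    strength: float = 1.0,
    n_genera: int = 10,
    n_windows: int = 30,
    outlier_position: int = 7,
    k: int = 13,
    base_seed: int = 0,
) -> float:
    """Fraction of seeded planted-outlier runs in which the planted window
    is flagged by the full scan -> Z -> PCA -> K-means pipeline."""
    from .cluster import WindowOutlierDetector
    from .scan import build_comparative_dataset, extract_windows, match_windows

    hits = 0
    for s in range(n_seeds):
        world = plant_outlier_query(
            n_genera=n_genera,
            n_windows=n_windows,
            outlier_positions=(outlier_position,),
            strength=strength,
            seed=base_seed + s,
        )
        windows = match_windows(extract_windows(world.query, frame=1), world.ref)
        ds = build_comparative_dataset(windows, world.genus_dbs)
        det = WindowOutlierDetector(k=k, seed=base_seed + s).fit(ds.Z)
        planted_col = next(
            idx for idx, w in enumerate(ds.windows) if w.index == outlier_position
        )
        hits += bool(det.outlier_mask_[planted_col])
    return hits / n_seeds


def load_example_query() -> str:
    """The 270 bp example query shipped with the package."""
    text = (
        resources.files("psfunc").joinpath("data/example_query.fasta").read_text()
    )
    return "".join(
        line.strip() for line in text.splitlines() if not line.startswith(">")
    )
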