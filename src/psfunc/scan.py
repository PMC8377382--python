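"""Query scanning: reading-frame windows and the comparative dataset Z.

A query DNA sequence is decomposed, per reading frame, into overlapping
3-codon 9-mer windows at codon stride.  Windows whose amino-acid trimer is
present in the trimer reference are "matching"; their per-genus trimer usage
biases form the comparative matrix Z (genera in rows, windows in columns).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Seq import reverse_complement

from .chargroups import char_trimer_of
from .codons import translate
from .refdb import TrimerRefDB
from .usage import GenusUsageDB

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")


def normalize_query(seq: str) -> str:
    """Uppercase and map U->T.  Other IUPAC codes are left in place; windows
    containing them are omitted during extraction rather than failing."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class WindowRecord:
    """One 3-codon 9-mer window of a query in a given reading frame.

    ``index`` is the zero-based positional ordinal of the window within the
    frame; ``nt_start`` the zero-based offset of its first nucleotide on the
    scanned strand (``nt_start = frame_offset + 3 * index``).
    """

    frame: int
    index: int
    nine_mer: str
    aa_trimer: str
    char_trimer: str
    nt_start: int

    @property
    def abbrev(self) -> str:
        """Short abbreviation, e.g. ``"3 NWT"``."""
        return f"{self.index} {self.aa_trimer}"

    @property
    def abbrev_long(self) -> str:
        """Long abbreviation, e.g. ``"3-EKD-NWT-AACTGGACC"``."""
        return f"{self.index}-{self.char_trimer}-{self.aa_trimer}-{self.nine_mer}"


def frame_offset(frame: int) -> int:
    if frame not in (1, 2, 3, 4, 5, 6):
        raise ValueError(f"frame must be 1..6, got {frame}")
    return (frame - 1) % 3


def extract_windows(seq: str, frame: int) -> list[WindowRecord]:
    """Extract all 3-codon windows of `seq` in one reading frame.

    Frames 1-3 scan the forward strand at offsets 0-2; frames 4-6 scan the
    reverse complement at offsets 0-2.  Windows containing non-ACGT symbols
    are omitted; the retained windows keep their positional ordinals, so
    indices stay comparable across references.
    """
    seq = normalize_query(seq)
    if frame >= 4:
        seq = reverse_complement(seq)
    off = frame_offset(frame)
    n_windows = max(0, (len(seq) - off) // 3 - 2)
    records = []
    for idx in range(n_windows):
        start = off + 3 * idx
        mer = seq[start : start + 9]
        if not _ACGT.issuperset(mer):
            logger.debug("frame %d window %d skipped (non-ACGT): %s", frame, idx, mer)
            continue
        aa = translate(mer)
        records.append(
            WindowRecord(
                frame=frame,
                index=idx,
                nine_mer=mer,
                aa_trimer=aa,
                char_trimer=char_trimer_of(aa),
                nt_start=start,
            )
        )
    return records


def match_windows(
    windows: Iterable[WindowRecord], ref: TrimerRefDB
) -> list[WindowRecord]:
    """Retain windows whose amino-acid trimer exists in the reference.

    Matching is at the trimer level; a 9-mer unobserved in a genus simply
    contributes bias 0 there.  Ordering is preserved and the operation is
    idempotent.
    """
    return [w for w in windows if w.aa_trimer in ref]


@dataclass
class ComparativeDataset:
    """Comparative matrix Z: genera (I) x matching windows (J) of biases."""

    Z: np.ndarray
    genus_labels: list[str]
    windows: list[WindowRecord]

    @property
    def n_genera(self) -> int:
        return self.Z.shape[0]

    @property
    def n_windows(self) -> int:
        return self.Z.shape[1]


def build_comparative_dataset(
    windows: Sequence[WindowRecord], genus_dbs: Sequence[GenusUsageDB]
) -> ComparativeDataset:
    """Assemble Z by looking up the trimer usage bias of every window in
    every genus.  Requires at least 2 genera and 2 matching windows (PCA
    needs both dimensions)."""
    if len(genus_dbs) < 2:
        raise ValueError(f"need at least 2 genera, got {len(genus_dbs)}")
    if len(windows) < 2:
        raise ValueError(
            f"query too short or no matches: {len(windows)} matching window(s), "
            "need at least 2"
        )
    Z = np.array(
        [[db.bias(w.aa_trimer, w.nine_mer) for w in windows] for db in genus_dbs],
        dtype=float,
    )
    return ComparativeDataset(
        Z=Z, genus_labels=[db.genus_id for db in genus_dbs], windows=list(windows)
    )
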