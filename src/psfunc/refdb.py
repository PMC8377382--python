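"""Trimer reference database: a three-level hierarchy.

characteristic trimer (12-letter alphabet)
  -> amino-acid trimer (3 residues)
    -> set of synonymous 3-codon DNA 9-mers

The amino-acid trimer list is an input (in the original workflow it is
curated from protein secondary-structure subunits); this module only builds
and serialises the hierarchy.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .chargroups import char_trimer_of
from .codons import SYNONYMOUS_CODONS, translate

logger = logging.getLogger(__name__)


@dataclass
class TrimerRefDB:
    """Hierarchy ``char_trimer -> aa_trimer -> set of 9-mers``."""

    entries: dict[str, dict[str, set[str]]] = field(default_factory=dict)

    @property
    def aa_trimers(self) -> set[str]:
        return {aa for level in self.entries.values() for aa in level}

    def __contains__(self, aa_trimer: str) -> bool:
        char = char_trimer_of(aa_trimer)
        return aa_trimer in self.entries.get(char, ())

    def add_aa_trimer(self, aa_trimer: str) -> None:
        char = char_trimer_of(aa_trimer)
        level = self.entries.setdefault(char, {})
        if aa_trimer in level:
            logger.info("duplicate amino-acid trimer %s merged", aa_trimer)
        else:
            level[aa_trimer] = set()

    def add_nine_mer(self, nine_mer: str) -> None:
        """Record an observed 9-mer under its (already present) trimer."""
        aa = translate(nine_mer)
        char = char_trimer_of(aa)
        level = self.entries.get(char)
        if level is None or aa not in level:
            raise KeyError(f"amino-acid trimer {aa} not in reference")
        level[aa].add(nine_mer)

    def nine_mers(self, aa_trimer: str) -> set[str]:
        return self.entries.get(char_trimer_of(aa_trimer), {}).get(aa_trimer, set())

    # -- serialisation (plain TSV: char_trimer, aa_trimer, nine_mer|-) ------

    def save(self, path: str | Path) -> None:
        lines = []
        for char in sorted(self.entries):
            for aa in sorted(self.entries[char]):
                mers = sorted(self.entries[char][aa])
                if not mers:
                    lines.append(f"{char}\t{aa}\t-")
                for mer in mers:
                    lines.append(f"{char}\t{aa}\t{mer}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TrimerRefDB":
        db = cls()
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            char, aa, mer = line.split("\t")
            level = db.entries.setdefault(char, {})
            level.setdefault(aa, set())
            if mer != "-":
                level[aa].add(mer)
        return db


def build_trimer_ref(
    aa_trimer_list: Iterable[str], expansion: str = "all_synonymous"
) -> TrimerRefDB:
    """Build a :class:`TrimerRefDB` from a list of amino-acid trimers.

    Parameters
    ----------
    aa_trimer_list : iterable of str
        3-residue strings (stop symbol allowed). Duplicates are merged.
    expansion : {"all_synonymous", "observed"}
        ``all_synonymous``: each trimer's 9-mer set is the full cartesian
        product of its residues' synonymous codons.  ``observed``: 9-mer sets
        start empty and are filled later from CDS scans
        (:meth:`TrimerRefDB.add_nine_mer`).
    """
    trimers = list(aa_trimer_list)
    if not trimers:
        raise ValueError("amino-acid trimer list is empty")
    if expansion not in ("all_synonymous", "observed"):
        raise ValueError(f"unknown expansion mode {expansion!r}")
    db = TrimerRefDB()
    for aa in trimers:
        db.add_aa_trimer(aa)
        if expansion == "all_synonymous":
            char = char_trimer_of(aa)
            db.entries[char][aa] = {
                "".join(codons)
                for codons in itertools.product(*(SYNONYMOUS_CODONS[r] for r in aa))
            }
    return db


def read_trimer_list(path: str | Path) -> list[str]:
    """Read a one-trimer-per-line text file."""
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
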