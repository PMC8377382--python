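"""Standard genetic code helpers (translation table 1).

The stop symbol ``*`` is treated as a first-class 21st residue so that
stop-containing windows can be counted (they map to characteristic group L).
"""

from __future__ import annotations

from Bio.Data import CodonTable

from .chargroups import STOP

_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: codon -> residue (incl. stop codons -> "*")
CODON_TO_RESIDUE: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_RESIDUE.update({codon: STOP for codon in _TABLE.stop_codons})

#: residue -> sorted tuple of synonymous codons
SYNONYMOUS_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _res in sorted(CODON_TO_RESIDUE.items()):
    SYNONYMOUS_CODONS.setdefault(_res, ())
    SYNONYMOUS_CODONS[_res] += (_codon,)

_ACGT = frozenset("ACGT")


def translate(nine_mer: str) -> str:
    """Translate a 9-nt window into its 3-residue trimer.

    Stop codons yield ``*``.  Only uppercase A/C/G/T are accepted; the caller
    is responsible for normalising case and U->T.
    """
    if len(nine_mer) != 9:
        raise ValueError(f"expected 9 nucleotides, got {len(nine_mer)}: {nine_mer!r}")
    if not _ACGT.issuperset(nine_mer):
        bad = sorted(set(nine_mer) - _ACGT)
        raise ValueError(f"non-ACGT symbol(s) {bad} in window {nine_mer!r}")
    return "".join(CODON_TO_RESIDUE[nine_mer[i : i + 3]] for i in (0, 3, 6))
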