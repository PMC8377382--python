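"""Reduced 12-letter amino-acid "characteristic" alphabet.

Each of the 20 standard residues plus the stop symbol (``*``) belongs to
exactly one of 12 physicochemical groups labelled ``A``..``L``.  A trimer of
residues rewritten in this alphabet is a *characteristic trimer* (char
trimer), the top level of the trimer reference hierarchy; with 12 letters
there are at most 12**3 = 1728 strings, of which 1296 exclude the stop group
in any position-free sense used by usage tables.
"""

from __future__ import annotations

STOP = "*"

#: group label -> member residues (stop codons form their own group L)
GROUP_MEMBERS: dict[str, str] = {
    "A": "KR",
    "B": "H",
    "C": "DE",
    "D": "ST",
    "E": "NQ",
    "F": "C",
    "G": "G",
    "H": "P",
    "I": "M",
    "J": "AILV",
    "K": "FWY",
    "L": STOP,
}

RESIDUE_TO_GROUP: dict[str, str] = {
    residue: group for group, members in GROUP_MEMBERS.items() for residue in members
}

GROUP_LABELS: tuple[str, ...] = tuple(GROUP_MEMBERS)


def classify_residue(residue: str) -> str:
    """Return the characteristic-group label (``A``..``L``) of one residue.

    Parameters
    ----------
    residue : str
        One-letter amino-acid code or the stop symbol ``*``.

    Raises
    ------
    ValueError
        If `residue` is not a standard one-letter code or ``*``.
    """
    try:
        return RESIDUE_TO_GROUP[residue]
    except KeyError:
        raise ValueError(
            f"unknown amino-acid symbol {residue!r}: expected one of "
            f"{''.join(sorted(RESIDUE_TO_GROUP))}"
        ) from None


def char_trimer_of(aa_trimer: str) -> str:
    """Rewrite a 3-residue trimer in the 12-letter group alphabet."""
    if len(aa_trimer) != 3:
        raise ValueError(f"expected a 3-residue trimer, got {aa_trimer!r}")
    return "".join(classify_residue(r) for r in aa_trimer)
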