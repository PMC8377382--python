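"""Per-genus usage-bias databases.

For each genus two families of relative-frequency tables are computed from
its CDS set:

* amino-acid trimer usage — frequency of a trimer among all reference
  trimers sharing its characteristic trimer (one table per char trimer);
* 3-codon usage — frequency of a specific 9-mer among all observed
  synonymous 9-mers of its amino-acid trimer (one table per trimer).

The *trimer usage bias* of a (trimer, 9-mer) pair is the product of the two,
the value that populates the comparative matrix Z.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .chargroups import char_trimer_of
from .codons import translate
from .refdb import TrimerRefDB

logger = logging.getLogger(__name__)

_ACGT = frozenset("ACGT")

CountTable = Counter  # keys: (aa_trimer, nine_mer)


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def scan_cds(cds_records: Iterable) -> Counter:
    """Count overlapping 3-codon windows (codon stride) over in-frame CDS.

    Accepts Biopython ``SeqRecord`` objects or ``(id, sequence)`` pairs.
    A trailing partial codon is truncated with a warning; windows containing
    non-ACGT letters are skipped.  Stop-containing windows are counted (the
    stop symbol is a first-class residue).
    """
    counts: Counter = Counter()
    for rec in cds_records:
        if hasattr(rec, "seq"):
            name, seq = rec.id, str(rec.seq)
        else:
            name, seq = rec
        seq = _normalize_seq(seq)
        if len(seq) % 3:
            logger.warning(
                "CDS %s length %d not divisible by 3; trailing %d nt truncated",
                name, len(seq), len(seq) % 3,
            )
            seq = seq[: len(seq) - len(seq) % 3]
        n_codons = len(seq) // 3
        for j in range(max(0, n_codons - 2)):
            window = seq[3 * j : 3 * j + 9]
            if not _ACGT.issuperset(window):
                continue
            counts[(translate(window), window)] += 1
    return counts


@dataclass
class GenusUsageDB:
    """Usage tables of one genus.

    Attributes
    ----------
    genus_id : str
    aa_trimer_usage : dict
        ``char_trimer -> {aa_trimer: relative frequency}``; each non-empty
        table sums to 1.
    codon9_usage : dict
        ``aa_trimer -> {nine_mer: relative frequency}``; each non-empty table
        sums to 1.
    counts : Counter
        Raw ``(aa_trimer, nine_mer)`` window counts backing both tables.
    """

    genus_id: str
    aa_trimer_usage: dict[str, dict[str, float]] = field(default_factory=dict)
    codon9_usage: dict[str, dict[str, float]] = field(default_factory=dict)
    counts: Counter = field(default_factory=Counter)
    meta: dict = field(default_factory=dict)

    def bias(self, aa_trimer: str, nine_mer: str) -> float:
        """Trimer usage bias = aa-trimer usage x 3-codon usage (missing -> 0)."""
        u = self.aa_trimer_usage.get(char_trimer_of(aa_trimer), {}).get(aa_trimer, 0.0)
        if u == 0.0:
            return 0.0
        return u * self.codon9_usage.get(aa_trimer, {}).get(nine_mer, 0.0)

    # -- on-disk layout: one directory per genus, two TSVs + JSON manifest --

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "aa_trimer_usage.tsv", "w") as fh:
            fh.write("char_trimer\taa_trimer\tusage\n")
            for char in sorted(self.aa_trimer_usage):
                for aa, u in sorted(self.aa_trimer_usage[char].items()):
                    fh.write(f"{char}\t{aa}\t{u:.17g}\n")
        with open(d / "codon9_usage.tsv", "w") as fh:
            fh.write("aa_trimer\tnine_mer\tusage\n")
            for aa in sorted(self.codon9_usage):
                for mer, u in sorted(self.codon9_usage[aa].items()):
                    fh.write(f"{aa}\t{mer}\t{u:.17g}\n")
        manifest = {
            "genus": self.genus_id,
            "window_count": int(sum(self.counts.values())),
            **self.meta,
        }
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, directory: str | Path) -> "GenusUsageDB":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        db = cls(genus_id=manifest.pop("genus"), meta=manifest)
        with open(d / "aa_trimer_usage.tsv") as fh:
            next(fh)
            for line in fh:
                char, aa, u = line.rstrip("\n").split("\t")
                db.aa_trimer_usage.setdefault(char, {})[aa] = float(u)
        with open(d / "codon9_usage.tsv") as fh:
            next(fh)
            for line in fh:
                aa, mer, u = line.rstrip("\n").split("\t")
                db.codon9_usage.setdefault(aa, {})[mer] = float(u)
        return db


def compute_genus_usage(
    genus_id: str, count_table: Counter, ref: TrimerRefDB
) -> GenusUsageDB:
    """Turn raw window counts into normalised usage tables for one genus.

    Amino-acid trimer usage is conditional on the trimer's characteristic
    group (count of the trimer over the total count of all reference trimers
    sharing its char trimer); 3-codon usage is conditional on the trimer
    (count of the 9-mer over the trimer's total).  Trimers absent from the
    reference are excluded and logged.  Zero denominators yield empty
    tables, never NaN.
    """
    ref_trimers = ref.aa_trimers
    aa_counts: Counter = Counter()
    kept: Counter = Counter()
    dropped: set[str] = set()
    for (aa, mer), n in count_table.items():
        if n < 0:
            raise ValueError(f"negative count for ({aa}, {mer})")
        if aa not in ref_trimers:
            dropped.add(aa)
            continue
        aa_counts[aa] += n
        kept[(aa, mer)] = n
    if dropped:
        logger.info(
            "genus %s: %d trimer(s) absent from reference excluded: %s",
            genus_id, len(dropped), ", ".join(sorted(dropped)[:10]),
        )

    db = GenusUsageDB(genus_id=genus_id, counts=kept)

    char_totals: Counter = Counter()
    for aa, n in aa_counts.items():
        char_totals[char_trimer_of(aa)] += n
    for aa, n in aa_counts.items():
        char = char_trimer_of(aa)
        if char_totals[char] > 0:
            db.aa_trimer_usage.setdefault(char, {})[aa] = n / char_totals[char]

    for (aa, mer), n in kept.items():
        if aa_counts[aa] > 0:
            db.codon9_usage.setdefault(aa, {})[mer] = n / aa_counts[aa]
    return db


def trimer_usage_bias(db: GenusUsageDB, aa_trimer: str, nine_mer: str) -> float:
    """Functional form of :meth:`GenusUsageDB.bias`."""
    return db.bias(aa_trimer, nine_mer)
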