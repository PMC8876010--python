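"""Hairpin precursor reference with mature-miRNA coordinate annotations.

A reference bundles precursor (hairpin) sequences with the coordinates of
the annotated mature miRNA on each precursor.  Mature coordinates are
0-based half-open on the hairpin, so ``hairpin[start:end]`` is the mature
sequence.  Sequences use the DNA alphabet (A/C/G/T, uppercase); RNA input
is transliterated (U -> T) on load.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

MATURE_COLUMNS = ["hairpin_id", "mature_id", "start", "end"]


@dataclass
class MatureAnnotation:
    hairpin_id: str
    mature_id: str
    start: int  # 0-based inclusive
    end: int    # 0-based exclusive


@dataclass
class HairpinReference:
    """Precursor sequences plus mature coordinate annotations."""

    hairpins: dict[str, str]
    matures: list[MatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        for ann in self.matures:
            hp = self.hairpins.get(ann.hairpin_id)
            if hp is None:
                raise ValueError(f"mature {ann.mature_id} references unknown hairpin {ann.hairpin_id}")
            if not (0 <= ann.start < ann.end <= len(hp)):
                raise ValueError(f"mature {ann.mature_id} coordinates outside hairpin {ann.hairpin_id}")

    def mature_sequence(self, mature_id: str) -> str:
        ann = self.mature_by_id(mature_id)
        return self.hairpins[ann.hairpin_id][ann.start:ann.end]

    def mature_by_id(self, mature_id: str) -> MatureAnnotation:
        for ann in self.matures:
            if ann.mature_id == mature_id:
                return ann
        raise KeyError(mature_id)

    def matures_on(self, hairpin_id: str) -> list[MatureAnnotation]:
        return [a for a in self.matures if a.hairpin_id == hairpin_id]

    @property
    def mature_ids(self) -> list[str]:
        return [a.mature_id for a in self.matures]

    # ---- serialization ----------------------------------------------------

    def write(self, fasta_path: str | Path, mature_tsv_path: str | Path) -> None:
        records = [SeqRecord(Seq(seq), id=hid, description="") for hid, seq in self.hairpins.items()]
        SeqIO.write(records, str(fasta_path), "fasta")
        df = pd.DataFrame(
            [(a.hairpin_id, a.mature_id, a.start, a.end) for a in self.matures],
            columns=MATURE_COLUMNS,
        )
        df.to_csv(mature_tsv_path, sep="\t", index=False)

    @classmethod
    def read(cls, fasta_path: str | Path, mature_tsv_path: str | Path) -> "HairpinReference":
        hairpins: dict[str, str] = {}
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            if rec.id in hairpins:
                raise ValueError(f"duplicate hairpin id {rec.id!r} in {fasta_path}")
            hairpins[rec.id] = str(rec.seq).upper().replace("U", "T")
        df = pd.read_csv(mature_tsv_path, sep="\t")
        matures = [
            MatureAnnotation(row.hairpin_id, row.mature_id, int(row.start), int(row.end))
            for row in df.itertuples(index=False)
        ]
        return cls(hairpins=hairpins, matures=matures)


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper().replace("U", "T") for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str] | Iterable[tuple[str, str]], path: str | Path) -> None:
    items = seqs.items() if isinstance(seqs, dict) else seqs
    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in items],
        str(path),
        "fasta",
    )
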