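"""Region annotation of antibody V-gene sequences.

An antibody variable domain is partitioned, by Kabat-derived codon
intervals, into framework regions (FR1-FR3) and complementarity-determining
regions (CDR1, CDR2).  Codons beyond FR3 belong to the V(D)J junction and
are tracked under the pseudo-region ``JUNCTION``: their germline origin
cannot be assigned reliably, so downstream mutation tallies exclude them.

Region boundaries are inputs, not computed: full Kabat numbering is out of
scope and the intervals are supplied explicitly (YAML or TSV), one
1-based inclusive codon interval per region.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

REGION_NAMES = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "JUNCTION")
FR_REGIONS = frozenset({"FR1", "FR2", "FR3"})
CDR_REGIONS = frozenset({"CDR1", "CDR2"})
JUNCTION = "JUNCTION"

DNA_ALPHABET = frozenset("ACGT")


class RegionMapError(ValueError):
    """Raised for invalid or inconsistent region interval definitions."""


@dataclass(frozen=True)
class RegionInterval:
    """One region as a 1-based, inclusive codon interval."""

    name: str
    codon_start: int
    codon_end: int

    def __post_init__(self) -> None:
        if self.name not in REGION_NAMES:
            raise RegionMapError(
                f"unknown region name {self.name!r}; expected one of {REGION_NAMES}"
            )
        if self.codon_start < 1 or self.codon_end < self.codon_start:
            raise RegionMapError(
                f"invalid interval for {self.name}: "
                f"[{self.codon_start}, {self.codon_end}]"
            )

    def __contains__(self, codon_index: int) -> bool:
        return self.codon_start <= codon_index <= self.codon_end

    @property
    def n_codons(self) -> int:
        return self.codon_end - self.codon_start + 1


class RegionMap:
    """Ordered, non-overlapping codon intervals labelling V-domain regions.

    Intervals must ascend and may leave gaps (unannotated codons map to
    ``JUNCTION`` by convention of :meth:`region_of`).
    """

    def __init__(self, intervals: Iterable[RegionInterval]):
        ivs = tuple(
            iv if isinstance(iv, RegionInterval) else RegionInterval(*iv)
            for iv in intervals
        )
        if not ivs:
            raise RegionMapError("region map needs at least one interval")
        seen = set()
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.codon_start <= prev.codon_end:
                raise RegionMapError(
                    f"intervals {prev.name} and {cur.name} overlap or are out of order"
                )
        for iv in ivs:
            if iv.name in seen:
                raise RegionMapError(f"duplicate region {iv.name}")
            seen.add(iv.name)
        self.intervals = ivs

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionMap) and self.intervals == other.intervals

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{iv.name}:{iv.codon_start}-{iv.codon_end}" for iv in self.intervals
        )
        return f"RegionMap({parts})"

    @property
    def last_codon(self) -> int:
        return self.intervals[-1].codon_end

    def region_of(self, codon_index: int) -> str:
        """Region name for a 1-based codon index; unannotated -> JUNCTION."""
        if codon_index < 1:
            raise RegionMapError(f"codon index must be >= 1, got {codon_index}")
        for iv in self.intervals:
            if codon_index in iv:
                return iv.name
        return JUNCTION

    def codons_in(self, region_names: Iterable[str]) -> list[int]:
        wanted = set(region_names)
        out: list[int] = []
        for iv in self.intervals:
            if iv.name in wanted:
                out.extend(range(iv.codon_start, iv.codon_end + 1))
        return out

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> list[dict]:
        return [
            {"region": iv.name, "codon_start": iv.codon_start, "codon_end": iv.codon_end}
            for iv in self.intervals
        ]

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "RegionMap":
        return cls(
            RegionInterval(r["region"], int(r["codon_start"]), int(r["codon_end"]))
            for r in records
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump({"regions": self.to_dict()}, sort_keys=False))

    @classmethod
    def from_yaml(cls, source: Union[str, Path, io.TextIOBase]) -> "RegionMap":
        if isinstance(source, io.TextIOBase):
            data = yaml.safe_load(source)
        else:
            data = yaml.safe_load(Path(source).read_text())
        return cls.from_records(data["regions"])

    def to_tsv(self, path: Union[str, Path]) -> None:
        lines = ["region\tcodon_start\tcodon_end"]
        lines += [f"{iv.name}\t{iv.codon_start}\t{iv.codon_end}" for iv in self.intervals]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "RegionMap":
        lines = Path(path).read_text().strip().splitlines()
        header = lines[0].split("\t")
        recs = [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]
        return cls.from_records(recs)


#: Kabat-style heavy-chain map used as the default for simulation: 98 codons
#: through the end of FR3, CDR2 being the longest hypervariable stretch.
DEFAULT_VH_REGION_MAP = RegionMap(
    [
        RegionInterval("FR1", 1, 30),
        RegionInterval("CDR1", 31, 35),
        RegionInterval("FR2", 36, 49),
        RegionInterval("CDR2", 50, 66),
        RegionInterval("FR3", 67, 98),
    ]
)


@dataclass(frozen=True)
class AnnotatedSequence:
    """A nucleotide V-gene sequence with its region annotation.

    ``nucleotides`` must be an in-frame DNA string (length divisible by 3,
    alphabet ACGT); ``regions`` maps codon indices to FR/CDR labels.
    """

    id: str
    nucleotides: str
    regions: RegionMap

    def __post_init__(self) -> None:
        seq = self.nucleotides.upper()
        object.__setattr__(self, "nucleotides", seq)
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-ACGT characters {sorted(bad)}")
        if len(seq) % 3 != 0:
            raise ValueError(f"{self.id}: length {len(seq)} not divisible by 3")
        if self.regions.last_codon > self.n_codons:
            raise RegionMapError(
                f"{self.id}: region map extends to codon {self.regions.last_codon} "
                f"but sequence has only {self.n_codons} codons"
            )

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def codon(self, codon_index: int) -> str:
        """1-based codon access."""
        if not 1 <= codon_index <= self.n_codons:
            raise IndexError(f"codon index {codon_index} out of range")
        i = (codon_index - 1) * 3
        return self.nucleotides[i : i + 3]

    def codons(self) -> list[str]:
        return [self.codon(i) for i in range(1, self.n_codons + 1)]

    def region_of_nt(self, nt_position: int) -> str:
        """Region of a 1-based nucleotide position."""
        return self.regions.region_of((nt_position - 1) // 3 + 1)

    def translate(self) -> str:
        from .mutations import translate_codon

        return "".join(translate_codon(c) for c in self.codons())
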