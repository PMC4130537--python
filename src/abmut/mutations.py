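"""Codon-aware classification of somatic mutations against a germline V gene.

Every nucleotide difference between a clone and its germline precursor is
classified three ways:

* by **region** — framework (FR1-FR3) vs CDR (CDR1, CDR2), with junction
  positions beyond FR3 excluded from tallies;
* by **mutation type** — replacement (R, amino acid changes) vs silent
  (S, synonymous), judged at the codon level so that two substitutions in
  one codon share a single verdict (germline codon vs final clone codon);
* by **substitution class** — transition (purine<->purine or
  pyrimidine<->pyrimidine) vs transversion.

An elevated R/S ratio in the CDRs relative to the FRs is the classical
signature of antigen-driven selection; the *inherent* R/S ratio of a
sequence (what a random single-nucleotide mutator would produce, ~2.9 for
random coding sequence) is the reference against which observed ratios are
judged, and is computed here by exhaustive enumeration of all nine
single-base neighbours of every codon.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table

from .regions import (
    CDR_REGIONS,
    DNA_ALPHABET,
    FR_REGIONS,
    JUNCTION,
    AnnotatedSequence,
    RegionMap,
)

TRANSITION = "transition"
TRANSVERSION = "transversion"
REPLACEMENT = "R"
SILENT = "S"

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

_CODON_TO_AA = dict(standard_dna_table.forward_table)
_CODON_TO_AA.update({c: "*" for c in standard_dna_table.stop_codons})

#: Regions whose per-region R/S columns appear in the mutation table,
#: in reporting order.
TABLE_REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")


class MutationAnalysisError(ValueError):
    pass


class AlignmentError(MutationAnalysisError):
    """Clone and germline are not comparable position-by-position."""


def translate_codon(codon: str) -> str:
    """Standard genetic code; stop codons translate to '*'."""
    codon = codon.upper()
    if len(codon) != 3 or set(codon) - DNA_ALPHABET:
        raise MutationAnalysisError(f"not an unambiguous DNA codon: {codon!r}")
    return _CODON_TO_AA[codon]


def classify_substitution(base_from: str, base_to: str) -> str:
    """Transition vs transversion for one base substitution."""
    base_from, base_to = base_from.upper(), base_to.upper()
    for b in (base_from, base_to):
        if b not in DNA_ALPHABET:
            raise MutationAnalysisError(f"not a DNA base: {b!r}")
    if base_from == base_to:
        raise MutationAnalysisError("identical bases are not a substitution")
    same_class = ({base_from, base_to} <= PURINES) or ({base_from, base_to} <= PYRIMIDINES)
    return TRANSITION if same_class else TRANSVERSION


def classify_codon_effect(codon_from: str, codon_to: str) -> str:
    """Replacement (R) vs silent (S) verdict for a codon change.

    A change creating or destroying a stop codon counts as R: the encoded
    residue differs.
    """
    if codon_from.upper() == codon_to.upper():
        raise MutationAnalysisError("identical codons have no R/S verdict")
    return REPLACEMENT if translate_codon(codon_from) != translate_codon(codon_to) else SILENT


@dataclass(frozen=True)
class MutationRecord:
    """One germline->clone nucleotide substitution, fully classified."""

    clone_id: str
    nt_position: int  # 1-based
    codon_index: int  # 1-based
    region: str
    base_from: str
    base_to: str
    titv: str
    rs: str
    codon_from: str
    codon_to: str
    aa_from: str
    aa_to: str


def compare_to_germline(
    germline: AnnotatedSequence,
    clone: Union[str, AnnotatedSequence],
    clone_id: Optional[str] = None,
    mask_nt_positions: Iterable[int] = (),
) -> list[MutationRecord]:
    """List every substitution in ``clone`` relative to ``germline``.

    Sequences must be pre-aligned to germline coordinates (no indels): a
    length mismatch is an :class:`AlignmentError`, not a trigger for
    alignment.  The R/S verdict of each record compares the full germline
    codon with the full clone codon, so multiple hits in one codon share
    one codon-level verdict.  ``mask_nt_positions`` (1-based) excludes
    positions whose substitution type cannot be determined (e.g. a
    sequence-source discrepancy) from the output.
    """
    if isinstance(clone, AnnotatedSequence):
        clone_seq = clone.nucleotides
        clone_id = clone_id or clone.id
    else:
        clone_seq = clone.upper()
        clone_id = clone_id or "clone"
    if len(clone_seq) != len(germline.nucleotides):
        raise AlignmentError(
            f"{clone_id}: length {len(clone_seq)} != germline length "
            f"{len(germline.nucleotides)}"
        )
    bad = set(clone_seq) - DNA_ALPHABET
    if bad:
        raise MutationAnalysisError(
            f"{clone_id}: ambiguity codes not supported: {sorted(bad)}"
        )
    masked = set(mask_nt_positions)
    records: list[MutationRecord] = []
    g = germline.nucleotides
    for pos0, (gb, cb) in enumerate(zip(g, clone_seq)):
        if gb == cb:
            continue
        pos = pos0 + 1
        if pos in masked:
            continue
        ci = pos0 // 3 + 1
        codon_from = germline.codon(ci)
        codon_to = clone_seq[(ci - 1) * 3 : ci * 3]
        records.append(
            MutationRecord(
                clone_id=clone_id,
                nt_position=pos,
                codon_index=ci,
                region=germline.regions.region_of(ci),
                base_from=gb,
                base_to=cb,
                titv=classify_substitution(gb, cb),
                rs=classify_codon_effect(codon_from, codon_to),
                codon_from=codon_from,
                codon_to=codon_to,
                aa_from=translate_codon(codon_from),
                aa_to=translate_codon(codon_to),
            )
        )
    return records


RECORD_COLUMNS = [
    "clone_id",
    "nt_position",
    "codon_index",
    "region",
    "base_from",
    "base_to",
    "titv",
    "rs",
    "codon_from",
    "codon_to",
    "aa_from",
    "aa_to",
]


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records], columns=RECORD_COLUMNS)
    return df.sort_values(["clone_id", "nt_position"]).reset_index(drop=True)


def tabulate_mutations(
    records: Iterable[MutationRecord],
    region_map: RegionMap,
    exclude_beyond_fr3: bool = True,
    count_unit: str = "nucleotide",
    clone_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-clone, per-region R/S counts plus Ti/Tv totals.

    ``count_unit='nucleotide'`` counts every base substitution (the
    default convention, since all instances of substitution within a codon
    are considered); ``'codon'`` counts one event per mutated codon, the
    codon-level R/S verdict being shared either way.  Junction records
    (beyond FR3) are dropped when ``exclude_beyond_fr3`` is set.
    ``clone_ids`` forces row order and guarantees all-zero rows for clones
    without mutations.
    """
    if count_unit not in ("nucleotide", "codon"):
        raise MutationAnalysisError(f"unknown count_unit {count_unit!r}")
    map_regions = {iv.name for iv in region_map} | {JUNCTION}
    records = list(records)
    for r in records:
        if r.region not in map_regions:
            raise MutationAnalysisError(
                f"record at nt {r.nt_position} has region {r.region!r} "
                "absent from the region map"
            )
    columns = (
        [f"{reg}_{cls}" for reg in TABLE_REGIONS for cls in (REPLACEMENT, SILENT)]
        + ["TotalFR_R", "TotalFR_S", "TotalCDR_R", "TotalCDR_S",
           "transitions", "transversions"]
    )
    ids = list(clone_ids) if clone_ids is not None else sorted({r.clone_id for r in records})
    table = pd.DataFrame(0, index=pd.Index(ids, name="clone"), columns=columns)
    by_clone_codon: dict[tuple[str, int], list[MutationRecord]] = {}
    for r in records:
        by_clone_codon.setdefault((r.clone_id, r.codon_index), []).append(r)
    for (cid, _), hits in by_clone_codon.items():
        if cid not in table.index:  # clone_ids restricts the tally
            continue
        region = hits[0].region
        if region == JUNCTION and exclude_beyond_fr3:
            continue
        counted = hits if count_unit == "nucleotide" else hits[:1]
        for r in counted:
            if region != JUNCTION:  # junction has no R/S bucket, Ti/Tv only
                table.loc[cid, f"{region}_{r.rs}"] += 1
            table.loc[cid, "transitions" if r.titv == TRANSITION else "transversions"] += 1
    add_marginal_totals(table)
    return table


def add_marginal_totals(table: pd.DataFrame) -> pd.DataFrame:
    """(Re)derive TotalFR/TotalCDR columns from the per-region columns."""
    for cls in (REPLACEMENT, SILENT):
        table[f"TotalFR_{cls}"] = sum(
            table[f"{reg}_{cls}"] for reg in TABLE_REGIONS if reg in FR_REGIONS
        )
        table[f"TotalCDR_{cls}"] = sum(
            table[f"{reg}_{cls}"] for reg in TABLE_REGIONS if reg in CDR_REGIONS
        )
    return table


class RSCounts(NamedTuple):
    """Replacement/silent counts from exhaustive single-hit enumeration."""

    r: int
    s: int

    @property
    def ratio(self) -> float:
        return float("inf") if self.s == 0 else self.r / self.s

    @property
    def infinite(self) -> bool:
        return self.s == 0


def inherent_rs_counts(
    sequence: Union[str, AnnotatedSequence],
    region_selection: Optional[Iterable[str]] = None,
) -> RSCounts:
    """Enumerate all 9 single-base substitutions of every selected codon.

    ``region_selection`` restricts the enumeration to named regions of an
    :class:`AnnotatedSequence`; ``None`` selects every codon.
    """
    if isinstance(sequence, AnnotatedSequence):
        if region_selection is not None:
            codon_idx = sequence.regions.codons_in(region_selection)
            codons = [sequence.codon(i) for i in codon_idx]
        else:
            codons = sequence.codons()
    else:
        seq = sequence.upper()
        if len(seq) % 3 != 0:
            raise MutationAnalysisError("sequence length not divisible by 3")
        if region_selection is not None:
            raise MutationAnalysisError(
                "region selection requires an AnnotatedSequence"
            )
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if not codons:
        raise MutationAnalysisError("empty codon selection")
    r = s = 0
    for codon in codons:
        aa = translate_codon(codon)
        for i in range(3):
            for b in "ACGT":
                if b == codon[i]:
                    continue
                mutant = codon[:i] + b + codon[i + 1 :]
                if translate_codon(mutant) == aa:
                    s += 1
                else:
                    r += 1
    return RSCounts(r, s)


def inherent_rs_ratio(
    sequence: Union[str, AnnotatedSequence],
    region_selection: Optional[Iterable[str]] = None,
) -> float:
    """R/S ratio of :func:`inherent_rs_counts`; +inf when no silent path exists."""
    return inherent_rs_counts(sequence, region_selection).ratio


# ---- FASTA / table I/O -------------------------------------------------


def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_mutation_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a per-region mutation-count table (TSV, 'clone' index column).

    Marginal Total columns are derived if absent, so a table carrying only
    the per-region R/S counts is sufficient.
    """
    df = pd.read_csv(path, sep="\t").set_index("clone")
    if "TotalFR_R" not in df.columns:
        add_marginal_totals(df)
    return df
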