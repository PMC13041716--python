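"""Sequence and table I/O, alphabet normalisation, shared coordinate conventions.

All sequences are held internally in the RNA alphabet (T is mapped to U on
read) because the pairing rules are stated in RNA terms (G:U wobbles).
Intervals on transcript regions are 0-based half-open, 5'->3'; positions on a
miRNA are 1-based from the 5' end, so "nucleotide 12" means the twelfth
nucleotide of the mature strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = frozenset("ACGU")
RNA_ALPHABET_N = frozenset("ACGUN")

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


class SequenceFormatError(ValueError):
    """Raised for malformed FASTA input (empty record, duplicate id, bad alphabet)."""


class TableSchemaError(ValueError):
    """Raised when a tabular input does not match its declared schema."""


def normalize_rna(seq: str, *, dna_to_rna: bool = True, allow_n: bool = False,
                  context: str = "") -> str:
    """Uppercase a sequence and map T->U; validate the resulting alphabet."""
    s = seq.upper()
    if dna_to_rna:
        s = s.replace("T", "U")
    allowed = RNA_ALPHABET_N if allow_n else RNA_ALPHABET
    bad = set(s) - allowed
    if bad:
        where = f" in {context}" if context else ""
        raise SequenceFormatError(
            f"invalid characters {sorted(bad)}{where}; expected RNA alphabet"
        )
    return s


def revcomp(seq: str) -> str:
    """Reverse complement in RNA space (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA: ~22-nt guide sequence plus bookkeeping annotations.

    ``normalizer_ids`` lists cotranscribed strands / cluster members whose
    expression is used to normalise this miRNA's expression (e.g. miR-335-5p
    for miR-335-3p); it never contains the miRNA itself.
    """

    mirna_id: str
    sequence: str
    family_id: str = ""
    normalizer_ids: tuple[str, ...] = ()
    species: str = ""

    def __post_init__(self) -> None:
        seq = normalize_rna(self.sequence, context=f"miRNA {self.mirna_id!r}")
        object.__setattr__(self, "sequence", seq)
        if not 18 <= len(seq) <= 26:
            raise ValueError(
                f"miRNA {self.mirna_id!r}: length {len(seq)} outside 18..26"
            )
        if self.mirna_id in self.normalizer_ids:
            raise ValueError(
                f"miRNA {self.mirna_id!r} lists itself as a normalizer"
            )
        object.__setattr__(self, "normalizer_ids", tuple(self.normalizer_ids))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TranscriptRegion:
    """A 3' UTR or lncRNA sequence on which sites are reported.

    Coordinates against ``sequence`` are 0-based half-open.  ``tpm`` is the
    transcript's abundance where known; ``None`` means unknown (treated as
    passing any expression filter).
    """

    transcript_id: str
    sequence: str
    gene_id: str = ""
    region_kind: str = "utr3"
    tpm: float | None = None

    def __post_init__(self) -> None:
        if self.region_kind not in ("utr3", "lncRNA"):
            raise ValueError(f"unknown region_kind {self.region_kind!r}")
        seq = normalize_rna(self.sequence, allow_n=True,
                            context=f"region {self.transcript_id!r}")
        if not seq:
            raise ValueError(f"region {self.transcript_id!r} is empty")
        object.__setattr__(self, "sequence", seq)
        if self.tpm is not None and self.tpm < 0:
            raise ValueError(f"region {self.transcript_id!r}: negative TPM")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ScoringParams:
    """Parameters of the 3'-complementarity point scheme.

    Defaults implement the published scheme: one point per Watson-Crick match
    after miRNA nucleotide 12; an extra 0.5 point for pairing at each of the
    penultimate and third-to-last nucleotides; 0.5 point for a G:U wobble at
    the last nucleotide (wobbles score nothing elsewhere); one point deducted
    per gap or mismatch nucleotide; offsets beyond 3 penalised 0.5 point per
    extra nucleotide.  The search window is the 30 nt immediately upstream
    (5') of the seed match on the target.
    """

    match_point: float = 1.0
    end_bonus: float = 0.5
    wobble_end_bonus: float = 0.5
    gap_penalty_per_nt: float = 1.0
    mismatch_penalty: float = 1.0
    offset_free: int = 3
    offset_penalty_per_nt: float = 0.5
    scored_from_position: int = 13
    search_from_position: int = 9
    window_len: int = 30

    def __post_init__(self) -> None:
        for name in ("match_point", "end_bonus", "wobble_end_bonus",
                     "gap_penalty_per_nt", "mismatch_penalty",
                     "offset_penalty_per_nt"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.scored_from_position >= self.search_from_position >= 9:
            raise ValueError(
                "require scored_from_position >= search_from_position >= 9"
            )
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet_policy: str = "dna_to_rna",
               allow_n: bool = True) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` in file order.

    Ids are taken verbatim up to the first whitespace.  Sequences are
    uppercased; with ``alphabet_policy="dna_to_rna"`` T is mapped to U, with
    ``"rna"`` a T is an error.  Duplicate ids and empty records are rejected.
    """
    if alphabet_policy not in ("rna", "dna_to_rna"):
        raise ValueError(f"unknown alphabet_policy {alphabet_policy!r}")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise SequenceFormatError(f"duplicate FASTA id {rid!r} in {path}")
        seen.add(rid)
        raw = str(rec.seq)
        if not raw:
            raise SequenceFormatError(f"empty sequence for record {rid!r} in {path}")
        seq = normalize_rna(raw, dna_to_rna=(alphabet_policy == "dna_to_rna"),
                            allow_n=allow_n, context=f"record {rid!r}")
        records.append((rid, seq))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path,
                width: int = 70) -> None:
    """Write ``(id, sequence)`` pairs as FASTA, wrapping at ``width`` columns."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_mirnas(fasta_path: str | Path,
                annotations: str | Path | pd.DataFrame | None = None,
                species: str = "") -> list[MiRNA]:
    """Read mature miRNAs from FASTA, optionally joining a TSV of annotations.

    The annotation table may carry ``mirna_id``, ``family_id`` and
    ``normalizer_ids`` (comma-separated list of cotranscribed miRNA ids).
    """
    ann: dict[str, dict] = {}
    if annotations is not None:
        df = annotations if isinstance(annotations, pd.DataFrame) else read_table(
            annotations,
            {"mirna_id": str, "family_id": str, "normalizer_ids": str},
            required=("mirna_id",),
        )
        for _, row in df.iterrows():
            norm = row.get("normalizer_ids", "")
            norm_ids = tuple(x for x in str(norm).split(",") if x) if pd.notna(norm) else ()
            ann[row["mirna_id"]] = {
                "family_id": row.get("family_id", "") or "",
                "normalizer_ids": norm_ids,
            }
    out = []
    for rid, seq in read_fasta(fasta_path, "dna_to_rna", allow_n=False):
        extra = ann.get(rid, {})
        out.append(MiRNA(mirna_id=rid, sequence=seq, species=species, **extra))
    return out


def read_regions(fasta_path: str | Path,
                 tpm: str | Path | pd.DataFrame | None = None,
                 region_kind: str = "utr3") -> list[TranscriptRegion]:
    """Read transcript regions from FASTA, optionally joining per-gene TPM.

    The TPM table needs columns ``transcript_id`` and ``tpm`` and may carry
    ``gene_id``; transcripts absent from the table get ``tpm=None``.
    """
    tpm_map: dict[str, float] = {}
    gene_map: dict[str, str] = {}
    if tpm is not None:
        df = tpm if isinstance(tpm, pd.DataFrame) else read_table(
            tpm, {"transcript_id": str, "gene_id": str, "tpm": float},
            required=("transcript_id", "tpm"),
        )
        for _, row in df.iterrows():
            tpm_map[row["transcript_id"]] = float(row["tpm"])
            if "gene_id" in df.columns and pd.notna(row.get("gene_id")):
                gene_map[row["transcript_id"]] = row["gene_id"]
    return [
        TranscriptRegion(
            transcript_id=rid,
            sequence=seq,
            gene_id=gene_map.get(rid, rid),
            region_kind=region_kind,
            tpm=tpm_map.get(rid),
        )
        for rid, seq in read_fasta(fasta_path)
    ]


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_table(path: str | Path, schema: dict[str, type],
               required: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a TSV with header and validate it against a column schema.

    ``schema`` maps column name -> python type (str/int/float/bool); columns
    in ``required`` (default: all of ``schema``) must be present.  Numeric
    cells that fail to parse are reported with their row and column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    req = tuple(schema) if required is None else tuple(required)
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise TableSchemaError(f"{path}: missing required column(s) {missing}")
    for col, typ in schema.items():
        if col not in df.columns:
            continue
        if typ is str:
            continue
        if typ is bool:
            df[col] = df[col].map(
                {"True": True, "False": False, "true": True, "false": False,
                 "1": True, "0": False}
            )
            if df[col].isna().any():
                row = int(df[df[col].isna()].index[0])
                raise TableSchemaError(
                    f"{path}: unparseable boolean in column {col!r}, row {row}"
                )
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad[bad].index[0])
            raise TableSchemaError(
                f"{path}: unparseable numeric cell in column {col!r}, row {row} "
                f"(value {df[col].iloc[row]!r})"
            )
        df[col] = converted.astype(float if typ is float else "Int64")
    return df


def write_table(df: pd.DataFrame, path: str | Path, float_format: str = "%.6g") -> None:
    """Write a DataFrame as a TSV with header (deterministic formatting)."""
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_sites_bed(sites: Sequence, path: str | Path) -> None:
    """Write seed matches as BED6: chrom=transcript_id, name=site_type, strand +."""
    lines = []
    for s in sites:
        if s.start < 0 or s.end < 0:
            raise ValueError(f"negative coordinate in site {s}")
        if s.end <= s.start:
            raise ValueError(f"end <= start in site {s}")
        lines.append(f"{s.transcript_id}\t{s.start}\t{s.end}\t{s.site_type}\t0\t+")
    Path(path).write_text("".join(line + "\n" for line in lines))
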