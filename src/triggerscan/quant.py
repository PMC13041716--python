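"""Small-RNA read counting and cotranscribed-strand normalisation.

Trimmed reads are assigned to miRNAs by exact match of their first 19 nt to a
dictionary built from the mature sequences; no mismatches are allowed.
miRNAs sharing a 19-nt prefix are merged into one group.  Reads matching
spike-in sequences are tallied separately and excluded from the counts-per-
million denominator, which is the total of assigned miRNA reads.

Because miRNA production varies clone to clone, a miRNA of interest is
normalised to cotranscribed strands from the same hairpin or cluster (e.g.
miR-335-3p to miR-335-5p): shared production noise multiplies both strands
and cancels in the ratio, leaving strand-specific effects such as
trigger-directed degradation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .io import MiRNA, normalize_rna

logger = logging.getLogger(__name__)

PREFIX_LEN = 19


def build_dictionary(mirnas: Sequence[MiRNA]) -> dict[str, str]:
    """Map each distinct 19-nt prefix to a miRNA group id.

    miRNAs whose first 19 nt are identical are indistinguishable to the
    assignment rule and are merged under a group id concatenating their
    (sorted) member ids with "/".
    """
    short = [m.mirna_id for m in mirnas if len(m.sequence) < PREFIX_LEN]
    if short:
        raise ValueError(f"miRNA(s) shorter than {PREFIX_LEN} nt: {short}")
    members: dict[str, list[str]] = {}
    for m in mirnas:
        members.setdefault(m.sequence[:PREFIX_LEN], []).append(m.mirna_id)
    return {prefix: "/".join(sorted(ids)) for prefix, ids in members.items()}


def assign_reads(reads: str | Path | Iterable[str],
                 dictionary: dict[str, str],
                 spike_ids: Sequence[str] = ()) -> pd.Series:
    """Count reads per miRNA group for one sample.

    ``reads`` is a FASTA/FASTQ path or an iterable of read sequences.  A read
    counts for a group iff its first 19 nt equal the group's key exactly;
    shorter or unmatched reads are tallied under ``_unassigned``.  Groups
    consisting solely of spike-in miRNAs are counted but flagged by the
    caller-supplied ``spike_ids`` when computing cpm (see
    :class:`MiRNACountMatrix`).
    """
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
        seqs: Iterable[str] = (str(rec.seq) for rec in SeqIO.parse(str(path), fmt))
    else:
        seqs = reads
    counts: dict[str, int] = {g: 0 for g in dictionary.values()}
    counts["_unassigned"] = 0
    for raw in seqs:
        try:
            seq = normalize_rna(raw, allow_n=True)
        except ValueError:
            logger.info("skipping malformed read %r", raw[:30])
            continue
        group = dictionary.get(seq[:PREFIX_LEN]) if len(seq) >= PREFIX_LEN else None
        counts[group if group is not None else "_unassigned"] += 1
    return pd.Series(counts, dtype=int)


def _spike_groups(columns: Iterable[str], spike_ids: Sequence[str]) -> set[str]:
    spikes = set(spike_ids)
    return {g for g in columns
            if g != "_unassigned" and set(g.split("/")) <= spikes and spikes}


@dataclass
class MiRNACountMatrix:
    """Sample x miRNA-group count matrix with condition labels.

    ``counts`` rows are samples; ``conditions`` maps sample -> label
    (e.g. "WT" / "mutant").  ``cpm`` rescales each sample to one million
    assigned miRNA reads after removing spike-in groups and the unassigned
    tally.
    """

    counts: pd.DataFrame
    conditions: dict[str, str]
    spike_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        missing = set(self.counts.index) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_samples(cls, sample_counts: dict[str, pd.Series],
                     conditions: dict[str, str],
                     spike_ids: Sequence[str] = ()) -> "MiRNACountMatrix":
        df = pd.DataFrame(sample_counts).T.fillna(0).astype(int)
        return cls(df, dict(conditions), tuple(spike_ids))

    @property
    def mirna_groups(self) -> list[str]:
        drop = _spike_groups(self.counts.columns, self.spike_ids)
        return [c for c in self.counts.columns
                if c != "_unassigned" and c not in drop]

    @property
    def cpm(self) -> pd.DataFrame:
        """Counts per million assigned miRNA reads (spike-ins removed)."""
        sub = self.counts[self.mirna_groups].astype(float)
        totals = sub.sum(axis=1)
        if (totals == 0).any():
            bad = list(totals[totals == 0].index)
            raise ValueError(f"no assigned miRNA reads in sample(s) {bad}")
        return sub.div(totals, axis=0) * 1e6

    def samples_with(self, condition: str) -> list[str]:
        return [s for s, c in self.conditions.items() if c == condition]


def _group_for(matrix: MiRNACountMatrix, mirna_id: str) -> str:
    for g in matrix.counts.columns:
        if mirna_id == g or mirna_id in g.split("/"):
            return g
    raise KeyError(f"miRNA {mirna_id!r} not found in count matrix")


def normalized_fold_change(matrix: MiRNACountMatrix, target: str,
                           normalizers: Sequence[str],
                           wt_samples: Sequence[str] | None = None,
                           combine: str = "geometric") -> pd.DataFrame:
    """Cotranscribed-strand-normalised expression and fold change vs WT.

    Per sample, ``value`` = cpm(target) / mean cpm of the normalizer strands
    (geometric mean by default), and ``fold_change_vs_wt`` = value divided by
    the mean value over WT samples - so the WT mean fold change is exactly 1.
    Zero normalizer cpm in any sample is an error (the ratio is undefined).
    """
    if combine not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown combine {combine!r}")
    if not normalizers:
        raise ValueError("at least one normalizer miRNA is required")
    cpm = matrix.cpm
    tgt_col = _group_for(matrix, target)
    norm_cols = [_group_for(matrix, n) for n in normalizers]
    for s in cpm.index:
        for n, col in zip(normalizers, norm_cols):
            if cpm.at[s, col] <= 0:
                raise ValueError(
                    f"normalizer {n!r} has zero cpm in sample {s!r}"
                )
    norm = cpm[norm_cols]
    if combine == "geometric":
        denom = np.exp(np.log(norm).mean(axis=1))
    else:
        denom = norm.mean(axis=1)
    value = cpm[tgt_col] / denom
    wt = (list(wt_samples) if wt_samples is not None
          else matrix.samples_with("WT"))
    if not wt:
        raise ValueError("no WT samples to normalise against")
    fold = value / value.loc[wt].mean()
    return pd.DataFrame({
        "sample": cpm.index,
        "condition": [matrix.conditions[s] for s in cpm.index],
        "value": value.to_numpy(),
        "fold_change_vs_wt": fold.to_numpy(),
    })
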