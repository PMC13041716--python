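"""Canonical seed-match discovery on transcript regions.

A canonical site is the Watson-Crick complement of the miRNA seed (nucleotides
2-7) in the target, optionally extended by pairing to nucleotide 8 (m8) and/or
an adenosine opposite nucleotide 1 (A1).  Site types:

    6mer     WC match to miRNA 2-7
    7mer-A1  WC match to 2-7 plus a target A opposite position 1
    7mer-m8  WC match to 2-8
    8mer     WC match to 2-8 plus a target A opposite position 1

On the target read 5'->3', the nucleotide pairing miRNA position 8 is the
5'-most of the site and the A opposite position 1 the 3'-most.  At a given
seed locus the single best (most subsuming) requested type is reported.
Wobble pairs are never accepted in the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io import MiRNA, TranscriptRegion, read_table, revcomp

logger = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
#: subsumption order, strongest first
SITE_PRIORITY = {t: i for i, t in enumerate(SITE_TYPES)}

DEFAULT_SITE_TYPES = frozenset({"8mer", "7mer-m8", "7mer-A1"})

_SITE_LEN = {"8mer": 8, "7mer-m8": 7, "7mer-A1": 7, "6mer": 6}


@dataclass(frozen=True)
class SeedMatch:
    """A canonical seed-match site, 0-based half-open on its region."""

    transcript_id: str
    mirna_id: str
    site_type: str
    start: int
    end: int
    from_conserved_table: bool = False

    def __post_init__(self) -> None:
        if self.site_type not in SITE_TYPES:
            raise ValueError(f"unknown site_type {self.site_type!r}")
        if self.end - self.start != _SITE_LEN[self.site_type]:
            raise ValueError(
                f"site_type {self.site_type} requires length "
                f"{_SITE_LEN[self.site_type]}, got [{self.start},{self.end})"
            )


def expected_site_sequence(mirna_seq: str, site_type: str) -> str:
    """The exact target substring (5'->3') a site of this type must equal."""
    if site_type == "6mer":
        return revcomp(mirna_seq[1:7])
    if site_type == "7mer-m8":
        return revcomp(mirna_seq[1:8])
    if site_type == "7mer-A1":
        return revcomp(mirna_seq[1:7]) + "A"
    if site_type == "8mer":
        return revcomp(mirna_seq[1:8]) + "A"
    raise ValueError(f"unknown site_type {site_type!r}")


def site_matches(mirna_seq: str, region_seq: str, site_type: str,
                 start: int, end: int) -> bool:
    """Does region[start:end) satisfy the site-type definition for this miRNA?"""
    if start < 0 or end > len(region_seq):
        return False
    return region_seq[start:end] == expected_site_sequence(mirna_seq, site_type)


def find_seed_matches(mirna: MiRNA, region: TranscriptRegion,
                      site_types: frozenset[str] | set[str] = DEFAULT_SITE_TYPES,
                      ) -> list[SeedMatch]:
    """Find all canonical seed matches of ``mirna`` in ``region``.

    At each seed locus (a WC match of the 6-nt core), the strongest satisfied
    type among ``site_types`` is reported; weaker types at the same locus are
    subsumed.  Sites are returned 5'->3' and never duplicated.  Loci whose
    candidate interval contains N are skipped.
    """
    unknown = set(site_types) - set(SITE_TYPES)
    if unknown:
        raise ValueError(f"unknown site type(s) {sorted(unknown)}")
    seq = region.sequence
    mseq = mirna.sequence
    core = revcomp(mseq[1:7])          # pairs miRNA 2-7; target 5'->3'
    m8_target = revcomp(mseq[7])       # target nt pairing miRNA position 8
    out: list[SeedMatch] = []
    pos = seq.find(core)
    while pos != -1:
        s = pos
        has_m8 = s >= 1 and seq[s - 1] == m8_target
        has_a1 = s + 6 < len(seq) and seq[s + 6] == "A"
        # strongest satisfied type that was requested
        if has_m8 and has_a1:
            satisfied = ["8mer", "7mer-m8", "7mer-A1", "6mer"]
        elif has_m8:
            satisfied = ["7mer-m8", "6mer"]
        elif has_a1:
            satisfied = ["7mer-A1", "6mer"]
        else:
            satisfied = ["6mer"]
        for st in satisfied:
            if st in site_types:
                if st in ("8mer", "7mer-m8"):
                    start, end = s - 1, s - 1 + _SITE_LEN[st]
                else:
                    start, end = s, s + _SITE_LEN[st]
                if "N" not in seq[start:end]:
                    out.append(SeedMatch(region.transcript_id, mirna.mirna_id,
                                         st, start, end))
                else:
                    logger.info("skipping N-containing site at %s:%d",
                                region.transcript_id, start)
                break
        pos = seq.find(core, pos + 1)
    # distinct loci can yield overlapping but never identical intervals
    out.sort(key=lambda m: (m.start, m.end))
    return out


def load_conserved_sites(table: str | Path | pd.DataFrame,
                         regions: dict[str, TranscriptRegion] | list[TranscriptRegion],
                         mirnas: list[MiRNA],
                         ) -> tuple[list[SeedMatch], list[dict]]:
    """Ingest a precomputed conserved-site table (TargetScan-style).

    Rows carry ``transcript_id, mirna_family, site_type, start, end``.  Each
    row is validated against the region sequence for every miRNA of the named
    family: the substring must satisfy the claimed site type.  Returns
    ``(sites, rejected)`` where each rejected entry records the row index and
    reason; invalid rows never raise.
    """
    if not isinstance(table, pd.DataFrame):
        table = read_table(
            table,
            {"transcript_id": str, "mirna_family": str, "site_type": str,
             "start": int, "end": int},
        )
    if isinstance(regions, list):
        regions = {r.transcript_id: r for r in regions}
    by_family: dict[str, list[MiRNA]] = {}
    for m in mirnas:
        by_family.setdefault(m.family_id, []).append(m)

    sites: list[SeedMatch] = []
    rejected: list[dict] = []

    def reject(idx, reason):
        rejected.append({"row": int(idx), "reason": reason})
        logger.warning("conserved-site row %d rejected: %s", idx, reason)

    for idx, row in table.iterrows():
        tid = row["transcript_id"]
        st = row["site_type"]
        region = regions.get(tid)
        if region is None:
            reject(idx, f"unknown transcript {tid!r}")
            continue
        if st not in SITE_TYPES:
            reject(idx, f"unknown site_type {st!r}")
            continue
        start, end = int(row["start"]), int(row["end"])
        if start < 0 or end > len(region) or end <= start:
            reject(idx, f"coordinates [{start},{end}) out of range for {tid!r}")
            continue
        fam = by_family.get(row["mirna_family"], [])
        if not fam:
            reject(idx, f"unknown miRNA family {row['mirna_family']!r}")
            continue
        matched = [m for m in fam
                   if site_matches(m.sequence, region.sequence, st, start, end)]
        if not matched:
            reject(idx, f"substring fails {st} definition for family "
                        f"{row['mirna_family']!r}")
            continue
        for m in matched:
            sites.append(SeedMatch(tid, m.mirna_id, st, start, end,
                                   from_conserved_table=True))
    return sites, rejected
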