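"""End-to-end candidate scan: sites -> 3' scores -> energies -> ranked table.

Two search branches are supported, mirroring how trigger candidates are
found in practice: a de novo scan for all canonical seed matches, and
rescoring of sites taken from a precomputed conserved-site table.  A site
present in both branches receives the same score, since both feed the same
scoring routine.  Candidates are filtered for host-transcript expression and
ranked per miRNA on two axes - the complementarity score (descending) and
the duplex free energy (ascending, more negative first) - with no combined
score invented.
"""

from __future__ import annotations

import logging
from typing import Sequence

import pandas as pd

from .io import MiRNA, ScoringParams, TranscriptRegion
from .sites import (SeedMatch, DEFAULT_SITE_TYPES, find_seed_matches,
                    load_conserved_sites)
from .scoring import (TriggerScore, best_pairing, duplex_energy,
                      duplex_operands, extract_window, render_pairing)

logger = logging.getLogger(__name__)

_COLUMNS = ["mirna_id", "transcript_id", "gene_id", "site_type", "start",
            "end", "from_conserved_table", "match_points", "end_bonus",
            "wobble_end_bonus", "gap_penalty", "mismatch_penalty", "offset",
            "offset_penalty", "total", "duplex_dG", "pairing_string", "tpm",
            "passed_expression_filter", "rank_by_score", "rank_by_dG"]


def _pairing_string(score: TriggerScore) -> str:
    """Compact encoding of the configuration, e.g. ``13|14|15:...`` ."""
    return ";".join(f"{p}{'|' if k == 'WC' else ':'}{t}"
                    for p, t, k in score.config.pairs)


def score_site(mirna: MiRNA, region: TranscriptRegion, seed: SeedMatch,
               params: ScoringParams = ScoringParams(),
               compute_energy: bool = True) -> TriggerScore:
    """Score one seed-matched site: best 3' pairing plus duplex energy."""
    window = extract_window(region, seed, params)
    score = best_pairing(mirna, window, seed, params)
    if compute_energy:
        target, mir3p = duplex_operands(mirna, region, seed, params)
        score = score.with_energy(duplex_energy(target, mir3p))
    return score


def scan(mirnas: Sequence[MiRNA], regions: Sequence[TranscriptRegion],
         site_source: str = "denovo",
         conserved_sites=None,
         params: ScoringParams = ScoringParams(),
         tpm_min: float = 1.0,
         site_types=DEFAULT_SITE_TYPES,
         compute_energy: bool = True,
         ) -> tuple[pd.DataFrame, dict[tuple, TriggerScore]]:
    """Scan all miRNAs against all regions and rank candidates per miRNA.

    Returns the candidate table and a map from
    ``(mirna_id, transcript_id, start, site_type)`` to the underlying
    :class:`TriggerScore` (for diagrams).  Records failing the expression
    filter are retained with ``passed_expression_filter=False`` and excluded
    from both rankings.
    """
    if site_source not in ("denovo", "conserved_table"):
        raise ValueError(f"unknown site_source {site_source!r}")
    region_map = {r.transcript_id: r for r in regions}
    mirna_map = {m.mirna_id: m for m in mirnas}

    sites: list[SeedMatch] = []
    if site_source == "denovo":
        for m in mirnas:
            n_found = 0
            for r in regions:
                found = find_seed_matches(m, r, site_types)
                n_found += len(found)
                sites.extend(found)
            if n_found == 0:
                logger.info("miRNA %s: no seed matches in any region",
                            m.mirna_id)
    else:
        if conserved_sites is None:
            raise ValueError("site_source='conserved_table' requires "
                             "conserved_sites")
        sites, rejected = load_conserved_sites(conserved_sites, region_map,
                                               list(mirnas))
        if rejected:
            logger.warning("%d conserved-site row(s) rejected", len(rejected))

    rows = []
    scores: dict[tuple, TriggerScore] = {}
    for seed in sites:
        mirna = mirna_map[seed.mirna_id]
        region = region_map[seed.transcript_id]
        ts = score_site(mirna, region, seed, params, compute_energy)
        key = (seed.mirna_id, seed.transcript_id, seed.start, seed.site_type)
        scores[key] = ts
        tpm = region.tpm
        rows.append({
            "mirna_id": seed.mirna_id,
            "transcript_id": seed.transcript_id,
            "gene_id": region.gene_id,
            "site_type": seed.site_type,
            "start": seed.start,
            "end": seed.end,
            "from_conserved_table": seed.from_conserved_table,
            "match_points": ts.match_points,
            "end_bonus": ts.end_bonus,
            "wobble_end_bonus": ts.wobble_end_bonus,
            "gap_penalty": ts.gap_penalty,
            "mismatch_penalty": ts.mismatch_penalty,
            "offset": ts.config.offset if ts.config.pairs else 0,
            "offset_penalty": ts.offset_penalty,
            "total": ts.total,
            "duplex_dG": ts.duplex_dG,
            "pairing_string": _pairing_string(ts),
            "tpm": tpm,
            "passed_expression_filter": tpm is None or tpm >= tpm_min,
        })
    df = pd.DataFrame(rows, columns=[c for c in _COLUMNS
                                     if c not in ("rank_by_score",
                                                  "rank_by_dG")])
    df["rank_by_score"] = pd.array([None] * len(df), dtype="Int64")
    df["rank_by_dG"] = pd.array([None] * len(df), dtype="Int64")
    if df.empty:
        return df, scores

    # deterministic ordering and per-miRNA dense ranks over filtered records
    for mid, sub in df.groupby("mirna_id"):
        passed = sub[sub["passed_expression_filter"]]
        by_score = passed.sort_values(
            by=["total", "match_points", "transcript_id", "start"],
            ascending=[False, False, True, True], kind="stable")
        df.loc[by_score.index, "rank_by_score"] = range(1, len(by_score) + 1)
        with_dg = passed[passed["duplex_dG"].notna()]
        by_dg = with_dg.sort_values(
            by=["duplex_dG", "transcript_id", "start"],
            ascending=[True, True, True], kind="stable")
        df.loc[by_dg.index, "rank_by_dG"] = range(1, len(by_dg) + 1)

    df = df.sort_values(
        by=["mirna_id", "total", "match_points", "transcript_id", "start"],
        ascending=[True, False, False, True, True], kind="stable",
    ).reset_index(drop=True)
    return df, scores


def report(records: pd.DataFrame, top_n: int = 10,
           scores: dict[tuple, TriggerScore] | None = None,
           ) -> tuple[str, str]:
    """Deterministic TSV plus a per-miRNA text summary of the top candidates."""
    tsv = records.to_csv(sep="\t", index=False, float_format="%.6g")
    lines = []
    for mid, sub in records.groupby("mirna_id", sort=True):
        top = sub[sub["passed_expression_filter"]].nsmallest(
            top_n, "rank_by_score")
        lines.append(f"== {mid}: top {len(top)} of "
                     f"{int(sub['passed_expression_filter'].sum())} "
                     f"expressed candidate site(s) ==")
        for _, row in top.iterrows():
            dg = ("n/a" if pd.isna(row["duplex_dG"])
                  else f"{row['duplex_dG']:.2f} kcal/mol")
            lines.append(
                f"#{int(row['rank_by_score'])} {row['transcript_id']} "
                f"[{int(row['start'])},{int(row['end'])}) {row['site_type']}"
                f"  total={row['total']:.2f} "
                f"(match {row['match_points']:.1f}, ends "
                f"{row['end_bonus'] + row['wobble_end_bonus']:.1f}, "
                f"penalties {row['gap_penalty'] + row['mismatch_penalty'] + row['offset_penalty']:.1f})"
                f"  dG={dg}  offset={int(row['offset'])}"
            )
            if scores is not None:
                key = (row["mirna_id"], row["transcript_id"],
                       int(row["start"]), row["site_type"])
                if key in scores and scores[key].config.pairs:
                    lines.append(render_pairing(scores[key]))
        lines.append("")
    return tsv, "\n".join(lines)
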