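"""Cross-species rescoring of a trigger site from a multiple alignment.

Given the aligned site region across species and each species' genomic
hairpin, the mature miRNA of each species is inferred as the minimal-
substitution match to the reference mature sequence, the species' site is
located by alignment-column projection, and the 3'-pairing score is
recomputed with the same scheme used for the reference.  Species whose seed
match is broken are reported as ``site_lost``; species whose mature miRNA
cannot be resolved as ``mirna_unresolved``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import MiRNA, ScoringParams, TranscriptRegion, normalize_rna
from .sites import SeedMatch, site_matches, _SITE_LEN
from .scoring import TriggerScore, best_pairing, extract_window


@dataclass(frozen=True)
class SpeciesAlignment:
    """Aligned site regions (gaps '-'), one row per species, equal lengths.

    ``reference_site`` is the seed-match interval in *degapped* coordinates of
    the reference row; the degapped reference row is the reference site
    region.
    """

    rows: dict[str, str]
    reference_species: str
    reference_site: SeedMatch

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        if self.reference_species not in self.rows:
            raise ValueError(
                f"reference species {self.reference_species!r} not in alignment"
            )
        cleaned = {}
        for sp, seq in self.rows.items():
            s = seq.upper().replace("T", "U")
            bad = set(s) - set("ACGUN-")
            if bad:
                raise ValueError(
                    f"alignment row {sp!r}: invalid characters {sorted(bad)}"
                )
            cleaned[sp] = s
        object.__setattr__(self, "rows", cleaned)


@dataclass(frozen=True)
class SpeciesSiteScore:
    """Per-species outcome of rescoring the reference site."""

    species: str
    mature_mirna: str | None
    seed_intact: bool
    trigger_score: TriggerScore | None
    status: str  # scored | site_lost | mirna_unresolved

    def __post_init__(self) -> None:
        scored = self.mature_mirna is not None and self.seed_intact
        if (self.status == "scored") != scored:
            raise ValueError("status inconsistent with mature_mirna/seed_intact")


def infer_mature_mirna(reference_mature: MiRNA | str, species_hairpin: str,
                       max_subst_frac: float = 0.25,
                       ref_position: int | None = None) -> str | None:
    """Predict a species' mature miRNA from its genomic hairpin sequence.

    The same-length substring of the hairpin minimising substitution
    (Hamming) distance to the reference mature is returned; ``None`` if even
    the best match differs at more than ``max_subst_frac`` of positions.
    Ties go to the start position closest to ``ref_position`` when given,
    else the leftmost.
    """
    ref = (reference_mature.sequence if isinstance(reference_mature, MiRNA)
           else normalize_rna(reference_mature))
    hairpin = normalize_rna(species_hairpin, allow_n=True)
    k = len(ref)
    if len(hairpin) < k:
        raise ValueError("hairpin shorter than the mature miRNA")
    best_d, best_pos = None, None
    for s in range(len(hairpin) - k + 1):
        d = sum(1 for a, b in zip(ref, hairpin[s:s + k]) if a != b)
        better = best_d is None or d < best_d
        if not better and d == best_d and ref_position is not None:
            if abs(s - ref_position) < abs(best_pos - ref_position):
                better = True
        if better:
            best_d, best_pos = d, s
    if best_d > max_subst_frac * k:
        return None
    return hairpin[best_pos:best_pos + k]


def _column_maps(row: str) -> tuple[list[int], list[int | None]]:
    """(degapped position -> column, column -> degapped position or None)."""
    pos_to_col: list[int] = []
    col_to_pos: list[int | None] = []
    p = 0
    for c, ch in enumerate(row):
        if ch == "-":
            col_to_pos.append(None)
        else:
            pos_to_col.append(c)
            col_to_pos.append(p)
            p += 1
    return pos_to_col, col_to_pos


def score_species(alignment: SpeciesAlignment,
                  per_species_mirnas: dict[str, str | MiRNA | None],
                  params: ScoringParams = ScoringParams(),
                  ) -> list[SpeciesSiteScore]:
    """Rescore the reference site in every species of the alignment.

    The species seed interval is the minimal degapped interval covering the
    alignment columns of the reference seed; the site is intact only if that
    substring still satisfies the reference site type for the species' own
    miRNA (an insertion inside the seed breaks it).  Intact sites are scored
    with the standard pipeline on the species' upstream window.
    """
    ref = alignment.reference_site
    ref_row = alignment.rows[alignment.reference_species]
    ref_pos_to_col, _ = _column_maps(ref_row)
    ref_degapped = ref_row.replace("-", "")
    if not (0 <= ref.start < ref.end <= len(ref_degapped)):
        raise ValueError("reference site outside the degapped reference row")
    col_lo = ref_pos_to_col[ref.start]
    col_hi = ref_pos_to_col[ref.end - 1]

    out: list[SpeciesSiteScore] = []
    for species in sorted(alignment.rows):
        row = alignment.rows[species]
        raw_mirna = per_species_mirnas.get(species)
        if raw_mirna is None:
            out.append(SpeciesSiteScore(species, None, False, None,
                                        "mirna_unresolved"))
            continue
        mseq = (raw_mirna.sequence if isinstance(raw_mirna, MiRNA)
                else normalize_rna(raw_mirna))
        degapped = row.replace("-", "")
        _, col_to_pos = _column_maps(row)
        covered = [col_to_pos[c] for c in range(col_lo, col_hi + 1)
                   if col_to_pos[c] is not None]
        intact = False
        start = end = None
        if covered:
            start, end = covered[0], covered[-1] + 1
            intact = (end - start == _SITE_LEN[ref.site_type]
                      and site_matches(mseq, degapped, ref.site_type, start, end))
        if not intact:
            out.append(SpeciesSiteScore(species, mseq, False, None, "site_lost"))
            continue
        region = TranscriptRegion(transcript_id=f"{ref.transcript_id}|{species}",
                                  sequence=degapped)
        seed = SeedMatch(region.transcript_id, ref.mirna_id, ref.site_type,
                         start, end)
        window = extract_window(region, seed, params)
        score = best_pairing(mseq, window, seed, params)
        out.append(SpeciesSiteScore(species, mseq, True, score, "scored"))
    return out


def covariation_report(scores: list[SpeciesSiteScore],
                       reference: TriggerScore,
                       reference_mirna: str | MiRNA | None = None,
                       ) -> pd.DataFrame:
    """Tabulate miRNA/site sequence differences and their pairing consequences.

    For every species and miRNA position where either the species miRNA or
    its paired window nucleotide differs from the reference, reports whether
    pairing at that position is preserved (compensatory change), lost, or
    gained relative to the reference configuration.  Seed positions are not
    tabulated (species with broken seeds are never scored).
    """
    if not any(s.status == "scored" for s in scores):
        raise ValueError("no scored species to report on")
    ref_mseq = (reference_mirna.sequence if isinstance(reference_mirna, MiRNA)
                else reference_mirna) or reference.mirna_sequence
    ref_pairs = {p: (t, k) for p, t, k in reference.config.pairs}
    rows = []
    for s in scores:
        if s.status != "scored":
            continue
        sp_pairs = {p: (t, k) for p, t, k in s.trigger_score.config.pairs}
        sp_mseq = s.mature_mirna
        sp_window = s.trigger_score.window
        for p in range(9, min(len(ref_mseq), len(sp_mseq)) + 1):
            ref_nt = ref_mseq[p - 1]
            sp_nt = sp_mseq[p - 1]
            ref_t = ref_pairs.get(p)
            sp_t = sp_pairs.get(p)
            ref_partner = reference.window[ref_t[0]] if ref_t else None
            sp_partner = sp_window[sp_t[0]] if sp_t else None
            mirna_diff = ref_nt != sp_nt
            site_diff = (ref_partner or "") != (sp_partner or "")
            if not (mirna_diff or site_diff):
                continue
            if ref_t and sp_t:
                outcome = "preserved"
            elif ref_t:
                outcome = "lost"
            elif sp_t:
                outcome = "gained"
            else:
                outcome = "unpaired"
            rows.append({
                "species": s.species,
                "mirna_pos": p,
                "ref_mirna_nt": ref_nt,
                "species_mirna_nt": sp_nt,
                "ref_target_nt": ref_partner or "",
                "species_target_nt": sp_partner or "",
                "mirna_changed": mirna_diff,
                "site_changed": site_diff,
                "pairing": outcome,
            })
    return pd.DataFrame(
        rows, columns=["species", "mirna_pos", "ref_mirna_nt",
                       "species_mirna_nt", "ref_target_nt", "species_target_nt",
                       "mirna_changed", "site_changed", "pairing"],
    )
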