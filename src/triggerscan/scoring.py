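"""3'-complementarity scoring of candidate TDMD trigger sites.

For a seed-matched site, the 30 nt immediately upstream (5') of the site on
the target are searched for the pairing configuration with the highest extent
of complementarity to the miRNA 3' region, under a point scheme:

* one point per Watson-Crick pair at miRNA positions after nucleotide 12;
* 0.5 bonus point for pairing (of either kind) at each of the penultimate and
  third-to-last miRNA nucleotides;
* G:U wobbles score nothing, except 0.5 point for a wobble at the very last
  miRNA nucleotide;
* one point deducted per gap nucleotide or mismatch inside the paired span;
* the seed-to-3'-pairing offset is free up to 3 nt and costs 0.5 point per
  further nucleotide.

The offset is the number of unpaired target nucleotides between the seed
match and the first 3' pair minus the number of unpaired miRNA nucleotides
between position 8 and the first 3'-paired position.  A positive offset means
a target loop larger than the miRNA loop; only offsets beyond +3 are
penalised (a 3' helix that simply begins deeper into the miRNA, as in typical
trigger architectures bridging positions 9-12, costs nothing).

Maximisation is a dynamic program over monotone (non-crossing, antiparallel)
pairings with linear per-nucleotide gap/mismatch costs; correctness is
defined by exhaustive enumeration over configurations, which the test suite
checks on small instances.  The companion energy metric delegates to the
RNAduplex algorithm (ViennaRNA) for the intermolecular nearest-neighbor
minimum free energy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .io import MiRNA, ScoringParams, TranscriptRegion, RNA_ALPHABET
from .sites import SeedMatch

#: (mirna_pos 1-based from the miRNA 5' end, target_pos 0-based in the
#: upstream window, kind "WC" | "wobble")
Pair = tuple[int, int, str]

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def pair_kind(mirna_nt: str, target_nt: str) -> str | None:
    """Classify a putative base pair: "WC", "wobble", or None (no pair)."""
    duo = (mirna_nt, target_nt)
    if duo in _WC:
        return "WC"
    if duo in _WOBBLE:
        return "wobble"
    return None


@dataclass(frozen=True)
class PairingConfig:
    """A 3'-pairing configuration between miRNA 3' region and upstream window.

    ``pairs`` are strictly monotone: miRNA positions increase while target
    positions decrease (antiparallel helix).  Gap and mismatch counts refer to
    nucleotides strictly inside the paired span; flanking unpaired sequence is
    handled by the offset alone.
    """

    pairs: tuple[Pair, ...]
    mirna_gap_nts: int = 0
    target_gap_nts: int = 0
    mismatches: int = 0
    offset: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def n_wc(self) -> int:
        return sum(1 for _, _, k in self.pairs if k == "WC")


EMPTY_CONFIG = PairingConfig(pairs=())


@dataclass(frozen=True)
class TriggerScore:
    """Decomposed 3'-pairing score of one seed-matched site.

    ``total`` always equals ``match_points + end_bonus + wobble_end_bonus -
    gap_penalty - mismatch_penalty - offset_penalty`` exactly.  ``window`` is
    the upstream target sequence the configuration refers to (pairs use
    0-based positions within it) and ``mirna_sequence`` the mature miRNA.
    """

    seed_match: SeedMatch | None
    config: PairingConfig
    match_points: float
    end_bonus: float
    wobble_end_bonus: float
    gap_penalty: float
    mismatch_penalty: float
    offset_penalty: float
    total: float
    duplex_dG: float | None = None
    mirna_sequence: str = ""
    window: str = ""

    def with_energy(self, dG: float | None) -> "TriggerScore":
        return replace(self, duplex_dG=dG)


def extract_window(region: TranscriptRegion, seed: SeedMatch,
                   params: ScoringParams = ScoringParams()) -> str:
    """The up-to-``window_len`` nt immediately 5' of the seed match on the target.

    This is the target stretch that can pair the miRNA 3' region; it may be
    shorter than ``window_len`` (or empty) near the region start.
    """
    if not (0 <= seed.start and seed.end <= len(region.sequence)):
        raise ValueError(f"seed {seed} outside region {region.transcript_id!r}")
    return region.sequence[max(0, seed.start - params.window_len):seed.start]


def _validate_pairs(pairs: Sequence[Pair], mirna_seq: str, window: str,
                    params: ScoringParams) -> tuple[Pair, ...]:
    ordered = tuple(sorted(pairs, key=lambda pr: pr[0]))
    last_p, last_t = None, None
    for p, t, kind in ordered:
        if not params.search_from_position <= p <= len(mirna_seq):
            raise ValueError(f"miRNA position {p} outside searchable range")
        if not 0 <= t < len(window):
            raise ValueError(f"target position {t} outside window")
        actual = pair_kind(mirna_seq[p - 1], window[t])
        if actual != kind:
            raise ValueError(
                f"pair ({p},{t}) declared {kind} but sequences give {actual}"
            )
        if last_p is not None and (p <= last_p or t >= last_t):
            raise ValueError("pairs are not strictly monotone/antiparallel")
        last_p, last_t = p, t
    return ordered


def config_from_pairs(pairs: Sequence[Pair], mirna_seq: str, window: str,
                      params: ScoringParams = ScoringParams()) -> PairingConfig:
    """Build a validated PairingConfig (gap/mismatch/offset bookkeeping) from pairs."""
    ordered = _validate_pairs(pairs, mirna_seq, window, params)
    if not ordered:
        return EMPTY_CONFIG
    mirna_gaps = target_gaps = mismatches = 0
    for (p1, t1, _), (p2, t2, _) in zip(ordered, ordered[1:]):
        a = p2 - p1 - 1          # unpaired miRNA nts between the pairs
        b = t1 - t2 - 1          # unpaired target nts between the pairs
        m = min(a, b)
        mismatches += m
        if a > b:
            mirna_gaps += a - b
        else:
            target_gaps += b - a
    p0, t0, _ = ordered[0]
    # unpaired target nts between seed and first 3' pair, minus unpaired
    # miRNA nts between position 8 and the first 3'-paired position
    offset = (len(window) - 1 - t0) - (p0 - 9)
    return PairingConfig(pairs=ordered, mirna_gap_nts=mirna_gaps,
                         target_gap_nts=target_gaps, mismatches=mismatches,
                         offset=offset)


def score_config(config: PairingConfig, mirna_seq: str,
                 params: ScoringParams = ScoringParams()) -> dict[str, float]:
    """Apply the point scheme to a configuration; returns the score components."""
    L = len(mirna_seq)
    match_points = end_bonus = wobble_end = 0.0
    for p, _, kind in config.pairs:
        if kind == "WC" and p >= params.scored_from_position:
            match_points += params.match_point
        if p in (L - 1, L - 2):
            end_bonus += params.end_bonus
        if p == L and kind == "wobble":
            wobble_end += params.wobble_end_bonus
    gap_penalty = params.gap_penalty_per_nt * (config.mirna_gap_nts
                                               + config.target_gap_nts)
    mismatch_penalty = params.mismatch_penalty * config.mismatches
    offset_penalty = 0.0
    if config.pairs:
        offset_penalty = params.offset_penalty_per_nt * max(
            0, config.offset - params.offset_free)
    total = (match_points + end_bonus + wobble_end
             - gap_penalty - mismatch_penalty - offset_penalty)
    return {
        "match_points": match_points,
        "end_bonus": end_bonus,
        "wobble_end_bonus": wobble_end,
        "gap_penalty": gap_penalty,
        "mismatch_penalty": mismatch_penalty,
        "offset_penalty": offset_penalty,
        "total": total,
    }


def score_pairs(mirna: MiRNA | str, window: str, pairs: Sequence[Pair],
                params: ScoringParams = ScoringParams(),
                seed: SeedMatch | None = None) -> TriggerScore:
    """Score an explicit pair list (the definitional scorer).

    Used for rescoring configurations produced elsewhere (generator truth
    labels, per-species configurations); ``best_pairing`` maximises this same
    quantity.
    """
    mseq = mirna.sequence if isinstance(mirna, MiRNA) else mirna
    config = config_from_pairs(pairs, mseq, window, params)
    comp = score_config(config, mseq, params)
    return TriggerScore(seed_match=seed, config=config, mirna_sequence=mseq,
                        window=window, **comp)


# ---------------------------------------------------------------------------
# maximisation
# ---------------------------------------------------------------------------

def best_pairing(mirna: MiRNA | str, window: str, seed: SeedMatch | None = None,
                 params: ScoringParams = ScoringParams()) -> TriggerScore:
    """The maximal-scoring 3'-pairing configuration for one site.

    Dynamic program over monotone pairings of miRNA positions
    ``search_from_position..L`` against the upstream window.  Among
    equal-total configurations the tie-break prefers more WC pairs, then
    smaller \\|offset\\|, then fewer gap nucleotides, then the configuration
    starting closest to the seed; it is fully deterministic.  If no
    configuration scores above zero the empty configuration (total 0) is
    returned - reported totals are never negative.
    """
    mseq = mirna.sequence if isinstance(mirna, MiRNA) else mirna
    L = len(mseq)
    if L < params.scored_from_position:
        raise ValueError(
            f"miRNA of length {L} shorter than scored_from_position "
            f"{params.scored_from_position}"
        )
    sf = params.search_from_position
    W = len(window)
    n = L - sf + 1
    if W == 0 or n <= 0:
        return score_pairs(mseq, window, (), params, seed)

    # i indexes miRNA position p = sf + i; j indexes target position
    # t = W-1-j (j grows walking 5' on the target, away from the seed).
    kinds = [[None] * W for _ in range(n)]
    for i in range(n):
        m_nt = mseq[sf + i - 1]
        for j in range(W):
            kinds[i][j] = pair_kind(m_nt, window[W - 1 - j])

    def pairval(i: int, j: int, kind: str) -> float:
        p = sf + i
        v = 0.0
        if kind == "WC" and p >= params.scored_from_position:
            v += params.match_point
        if p in (L - 1, L - 2):
            v += params.end_bonus
        if p == L and kind == "wobble":
            v += params.wobble_end_bonus
        return v

    shift = sf - 9  # offset counts unpaired miRNA nts from position 8
    gap = params.gap_penalty_per_nt
    mm = params.mismatch_penalty

    # DP cells hold tie-break tuples (total, n_wc, -|offset|, -gap_nts,
    # t_first); lexicographic order is preserved under addition, so the
    # recurrence maximises totals and resolves ties simultaneously.
    # M[i][j]: best configuration whose first pair (closest to the seed on
    # the target, lowest miRNA position) is... rather whose *last processed*
    # pair is (i, j); G relays between pairs paying per-nucleotide costs.
    M = [[None] * W for _ in range(n)]
    G = [[None] * W for _ in range(n)]
    M_par = [[None] * W for _ in range(n)]
    G_par = [[None] * W for _ in range(n)]

    for i in range(n):
        for j in range(W):
            kind = kinds[i][j]
            if kind is not None:
                off = j - i - shift
                start_total = pairval(i, j, kind) - params.offset_penalty_per_nt * max(
                    0, off - params.offset_free)
                start = (start_total, 1 if kind == "WC" else 0, -abs(off),
                         0, W - 1 - j)
                best, par = start, ("start",)
                if i > 0 and j > 0 and G[i - 1][j - 1] is not None:
                    g = G[i - 1][j - 1]
                    cand = (g[0] + pairval(i, j, kind),
                            g[1] + (1 if kind == "WC" else 0),
                            g[2], g[3], g[4])
                    if cand > best:
                        best, par = cand, ("relay", i - 1, j - 1)
                M[i][j], M_par[i][j] = best, par
            # relay cell: best ending at some pair (i',j') <= (i,j) plus the
            # cost of the unpaired nucleotides up to (i, j)
            best, par = None, None
            if M[i][j] is not None:
                best, par = M[i][j], ("pair", i, j)
            for (ii, jj, cost, tag) in (
                (i - 1, j, gap, "gx"),
                (i, j - 1, gap, "gy"),
                (i - 1, j - 1, mm, "mmstep"),
            ):
                if ii >= 0 and jj >= 0 and G[ii][jj] is not None:
                    g = G[ii][jj]
                    cand = (g[0] - cost, g[1], g[2],
                            g[3] - (1 if tag in ("gx", "gy") else 0), g[4])
                    if best is None or cand > best:
                        best, par = cand, ("step", ii, jj)
            G[i][j], G_par[i][j] = best, par

    # best over all end pairs (trailing unpaired sequence is free)
    best_cell, best_val = None, None
    for i in range(n):
        for j in range(W):
            v = M[i][j]
            if v is not None and (best_val is None or v > best_val):
                best_val, best_cell = v, (i, j)

    if best_val is None or best_val[0] <= 1e-12:
        return score_pairs(mseq, window, (), params, seed)

    # reconstruct the pair list
    pairs: list[Pair] = []
    i, j = best_cell
    while True:
        pairs.append((sf + i, W - 1 - j, kinds[i][j]))
        par = M_par[i][j]
        if par[0] == "start":
            break
        _, gi, gj = par
        while True:
            gpar = G_par[gi][gj]
            if gpar[0] == "pair":
                i, j = gpar[1], gpar[2]
                break
            _, gi, gj = gpar
    pairs.reverse()
    return score_pairs(mseq, window, pairs, params, seed)


# ---------------------------------------------------------------------------
# duplex energy
# ---------------------------------------------------------------------------

def duplex_energy(target_seq: str, mirna_region: str) -> float | None:
    """Intermolecular minimum free energy (kcal/mol) of the two strands.

    Nearest-neighbor hybridisation energy without intramolecular structure,
    computed with the RNAduplex algorithm of ViennaRNA.  Returns ``None``
    when no stabilising duplex exists (no negative-energy pairing).
    """
    import RNA

    for name, s in (("target", target_seq), ("miRNA region", mirna_region)):
        if not s:
            raise ValueError(f"{name} sequence is empty")
        bad = set(s) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{name} contains non-RNA characters {sorted(bad)}")
    d = RNA.duplexfold(target_seq, mirna_region)
    if "(" not in d.structure or d.energy >= 0:
        return None
    return round(d.energy, 2)


def duplex_operands(mirna: MiRNA, region: TranscriptRegion, seed: SeedMatch,
                    params: ScoringParams = ScoringParams()) -> tuple[str, str]:
    """The two strands the energy co-metric is computed on.

    Target operand: upstream window plus the seed-match substring; miRNA
    operand: positions ``search_from_position..L`` (the 3' region).
    """
    window = extract_window(region, seed, params)
    target = window + region.sequence[seed.start:seed.end]
    return target, mirna.sequence[params.search_from_position - 1:]


# ---------------------------------------------------------------------------
# pairing diagrams
# ---------------------------------------------------------------------------

def render_pairing(score: TriggerScore) -> str:
    """Three-line text diagram of a configuration.

    Target window 5'->3' on top, pairing symbols in the middle ("|" WC,
    ":" wobble), miRNA 3'->5' on the bottom.  Every window nucleotide and
    every searchable miRNA nucleotide appears exactly once, with "-" padding
    opposite single-stranded stretches, so ``parse_pairing`` recovers the
    pair list exactly.
    """
    window = score.window
    mseq = score.mirna_sequence
    if not mseq:
        raise ValueError("TriggerScore carries no miRNA sequence")
    # searchable miRNA region rendered 3'->5'
    sf = min((p for p, _, _ in score.config.pairs), default=9)
    sf = min(sf, 9)
    L = len(mseq)
    pairs = sorted(score.config.pairs, key=lambda pr: pr[1])  # by target pos
    top, mid, bot = [], [], []
    ti = 0            # next target position to render
    mp = L            # next miRNA position to render (descending)

    def emit(t_nt, sym, m_nt):
        top.append(t_nt)
        mid.append(sym)
        bot.append(m_nt)

    def advance(t_until: int, m_until: int):
        """Render unpaired target positions < t_until and miRNA positions > m_until."""
        nonlocal ti, mp
        a = mp - m_until          # unpaired miRNA nts
        b = t_until - ti          # unpaired target nts
        for _ in range(min(a, b)):
            emit(window[ti], " ", mseq[mp - 1])
            ti += 1
            mp -= 1
        while ti < t_until:
            emit(window[ti], " ", "-")
            ti += 1
        while mp > m_until:
            emit("-", " ", mseq[mp - 1])
            mp -= 1

    for p, t, kind in pairs:
        advance(t, p)
        emit(window[t], "|" if kind == "WC" else ":", mseq[p - 1])
        ti += 1
        mp -= 1
    advance(len(window), sf - 1)
    return (f"target 5'-{''.join(top)}-3'\n"
            f"          {''.join(mid)}\n"
            f" miRNA 3'-{''.join(bot)}-5'")


def parse_pairing(diagram: str, mirna_len: int) -> tuple[Pair, ...]:
    """Invert :func:`render_pairing`: recover the pair list from a diagram."""
    lines = diagram.splitlines()
    if len(lines) != 3:
        raise ValueError("diagram must have exactly three lines")
    top = lines[0].removeprefix("target 5'-").removesuffix("-3'")
    mid = lines[1][10:].ljust(len(top))
    bot = lines[2].removeprefix(" miRNA 3'-").removesuffix("-5'")
    ti, mp = 0, mirna_len
    pairs: list[Pair] = []
    for t_ch, sym, m_ch in zip(top, mid, bot):
        t_here = t_ch not in "- "
        m_here = m_ch not in "- "
        if sym in "|:":
            if not (t_here and m_here):
                raise ValueError("pairing symbol over a padded column")
            pairs.append((mp, ti, "WC" if sym == "|" else "wobble"))
        if t_here:
            ti += 1
        if m_here:
            mp -= 1
    return tuple(sorted(pairs))
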