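"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is a pure function of its configuration and seed, so
identical calls give byte-identical outputs.  Implanted trigger sites are
written as the exact antisense nucleotides of the requested architecture
(scored matches, wobbles, bulges, offset), which guarantees the truth labels
rather than sampling until a score is met; flanking sequence next to an
implant is chosen to not extend the intended helix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MiRNA, ScoringParams, TranscriptRegion, revcomp
from .sites import SeedMatch
from .conservation import SpeciesAlignment
from .quant import MiRNACountMatrix

_NTS = np.array(list("ACGU"))
_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}
_WOBBLE_PARTNER = {"G": "U", "U": "G"}


def _partners(mirna_nt: str, include_wobble: bool = True) -> set[str]:
    out = {_WC_PARTNER[mirna_nt]}
    if include_wobble and mirna_nt in _WOBBLE_PARTNER:
        out.add(_WOBBLE_PARTNER[mirna_nt])
    return out


def random_rna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random RNA at the stated GC content (G and C equiprobable, likewise A/U)."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_NTS, size=length, p=p))


def _safe_nt(rng: np.random.Generator, avoid: set[str]) -> str:
    """A nucleotide outside ``avoid`` (falls back to any nt if none is safe)."""
    choices = [n for n in "ACGU" if n not in avoid]
    if not choices:
        choices = [n for n in "ACGU" if n != _WC_PARTNER.get(next(iter(avoid)), "")]
    return str(rng.choice(np.array(choices)))


@dataclass(frozen=True)
class TriggerSpec:
    """Requested architecture of one implanted trigger site.

    ``n_scored_matches`` WC pairs anchored at the miRNA 3' end (as in known
    trigger architectures, which pair through the 3' terminus), with
    ``n_wobbles`` additional covered positions realised as G:U pairs,
    ``bulge_nts`` extra target nucleotides bulged inside the helix, and the
    stated seed-to-3'-pairing ``offset`` (>= 0).  ``host_region`` picks the
    region index; None lets the generator choose.
    """

    mirna_id: str
    n_scored_matches: int
    n_wobbles: int = 0
    bulge_nts: int = 0
    offset: int = 0
    host_region: int | None = None


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic transcriptome and downstream tables.

    Defaults emulate a desk-scale transcriptome scan (a few hundred ~500-nt
    UTRs at balanced GC), lognormal expression, a small negative shift of
    predicted targets in the differential-expression table, negative-binomial
    miRNA counts with shared clone-to-clone production noise, and a star
    phylogeny for site conservation.
    """

    seed: int = 0
    # transcriptome
    n_regions: int = 500
    region_len_log10_mean: float = 2.7
    region_len_log10_sd: float = 0.15
    gc_content: float = 0.5
    n_mirnas: int = 1
    mirna_len: int = 22
    trigger_specs: tuple[TriggerSpec, ...] = ()
    decoy_seed_rate: float = 0.25
    tpm_log10_mean: float = 1.3
    tpm_log10_sd: float = 0.6
    # differential-expression table
    n_genes: int = 10000
    frac_targets: float = 0.10
    de_shift: float = 0.2
    de_noise: float = 0.3
    context_effect: float = 0.0
    utr_len_log10_mean: float = 2.9
    utr_len_log10_sd: float = 0.4
    de_tpm_log10_mean: float = 1.8
    de_tpm_log10_sd: float = 0.6
    # sRNA counts
    nb_dispersion: float = 100.0
    clone_noise_factor: float = 1.5
    # phylogeny
    n_species: int = 20
    substitution_rate: float = 0.05
    indel_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("decoy_seed_rate", "frac_targets", "gc_content",
                     "substitution_rate", "indel_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.de_shift < 0 or self.de_noise < 0:
            raise ValueError("de_shift and de_noise must be >= 0")


# ---------------------------------------------------------------------------
# transcriptome with implanted triggers
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTranscriptome:
    mirnas: list[MiRNA]
    regions: list[TranscriptRegion]
    tpm: pd.DataFrame     # transcript_id, gene_id, tpm
    truth: pd.DataFrame   # implanted sites with intended score components


def inert_filler_candidates(mirna_seq: str,
                            params: ScoringParams = ScoringParams()
                            ) -> list[str]:
    """Nucleotides that can pad a window without improving any configuration.

    A filler nucleotide is inert when it Watson-Crick pairs no scored miRNA
    position and wobble-pairs none of the three bonus-carrying terminal
    positions; stretches of such a nucleotide can then only form
    zero-point wobbles, which never change the optimal score.
    """
    L = len(mirna_seq)
    scored = set(mirna_seq[params.scored_from_position - 1:])
    terminal = {mirna_seq[p - 1] for p in (L, L - 1, L - 2)}
    out = []
    for nt in "ACGU":
        if any(_WC_PARTNER[m_nt] == nt for m_nt in scored):
            continue
        if any(_WOBBLE_PARTNER.get(m_nt) == nt for m_nt in terminal):
            continue
        out.append(nt)
    return out


def make_mirnas(cfg: SimConfig, rng: np.random.Generator) -> list[MiRNA]:
    """Random mature miRNAs suitable for trigger implantation.

    Rejection-samples sequences until the seed is non-degenerate, the 19-nt
    prefix is unique within the set, and an inert filler nucleotide exists
    (see :func:`inert_filler_candidates`) - the property that lets
    implanted-trigger truth labels be exact.
    """
    out: list[MiRNA] = []
    prefixes: set[str] = set()
    for i in range(cfg.n_mirnas):
        while True:
            seq = random_rna(rng, cfg.mirna_len, cfg.gc_content)
            # shift-self-similar 3' regions (period 1 or 2) let the helix
            # slide between registers and defeat exact truth labels
            three_prime = seq[12:]
            low_complexity = False
            for lag, max_run in ((1, 2), (2, 3)):
                run = 0
                for j in range(len(three_prime) - lag):
                    run = run + 1 if three_prime[j] == three_prime[j + lag] else 0
                    if run > max_run:
                        low_complexity = True
                        break
            if (len(set(seq[1:8])) >= 3 and seq[:19] not in prefixes
                    and not low_complexity
                    and inert_filler_candidates(seq)):
                break
        prefixes.add(seq[:19])
        out.append(MiRNA(mirna_id=f"miR-s{i + 1}", sequence=seq,
                         family_id=f"fam-s{i + 1}"))
    return out


def _inert_nt(rng: np.random.Generator, mirna_seq: str,
              in_register: int | None, params: ScoringParams) -> str:
    """A filler nucleotide chosen to not improve any pairing configuration.

    Strictly avoids WC partners of every scored miRNA position and wobble
    partners of the in-register position and of the bonus-carrying terminal
    positions; among the remaining candidates (or, if none remain, among all
    four) the least pairing-prone is taken, ties broken at random.
    """
    L = len(mirna_seq)
    scored = mirna_seq[params.scored_from_position - 1:]
    terminal = {mirna_seq[p - 1] for p in (L, L - 1, L - 2)}
    # only pairings that could *raise* the total are forbidden in register:
    # a contiguous WC at a scored position, or a contiguous wobble at a
    # bonus-carrying terminal position
    reg_avoid: set[str] = set()
    if in_register is not None and in_register <= L:
        q_nt = mirna_seq[in_register - 1]
        if in_register >= params.scored_from_position:
            reg_avoid.add(_WC_PARTNER[q_nt])
        if in_register >= L - 2 and q_nt in _WOBBLE_PARTNER:
            reg_avoid.add(_WOBBLE_PARTNER[q_nt])
    best, best_w = [], None
    for nt in "ACGU":
        w = 0
        if nt in reg_avoid:       # would extend the helix without any gap
            w += 10000
        # a WC pair at a bonus-carrying terminal position repays a gap
        if nt in (_WC_PARTNER[mirna_seq[L - 2]], _WC_PARTNER[mirna_seq[L - 3]]):
            w += 5000
        if nt == _WC_PARTNER[mirna_seq[L - 1]]:
            w += 2000
        w += 100 * sum(1 for m_nt in scored if _WC_PARTNER[m_nt] == nt)
        w += 3 * sum(1 for m_nt in terminal
                     if _WOBBLE_PARTNER.get(m_nt) == nt)
        w += sum(1 for m_nt in scored if _WOBBLE_PARTNER.get(m_nt) == nt)
        if best_w is None or w < best_w:
            best, best_w = [nt], w
        elif w == best_w:
            best.append(nt)
    return str(rng.choice(np.array(best)))


def build_trigger_site(mirna: MiRNA, spec: TriggerSpec,
                       rng: np.random.Generator,
                       params: ScoringParams = ScoringParams(),
                       ) -> tuple[str, str, dict]:
    """Construct (upstream, seed_site, intended-components) for one trigger.

    ``upstream`` is exactly ``window_len`` nt of target sequence (5'->3'):
    inert filler, then the 3'-pairing segment realising the requested
    architecture, then the offset spacer abutting the 8mer ``seed_site``.
    Because the whole search window is constructed (filler included), the
    intended configuration is the maximal-scoring one and the returned
    components are true labels for trigger-like architectures (several
    scored matches; see the package methods note).
    """
    m = mirna.sequence
    L = len(m)
    k = spec.n_scored_matches + spec.n_wobbles
    # the helix is anchored at the miRNA 3' end, as in known triggers
    first = L - k + 1
    if k < 1 or first < params.scored_from_position:
        raise ValueError(f"trigger would cover positions {first}..{L}, "
                         f"below scored position {params.scored_from_position}")
    if spec.offset < 0:
        raise ValueError("implanted offset must be >= 0")
    covered = list(range(first, L + 1))               # miRNA positions
    wobble_eligible = [p for p in covered[:-1] if m[p - 1] in _WOBBLE_PARTNER
                       and p != L]
    if spec.n_wobbles > len(wobble_eligible):
        raise ValueError(
            f"cannot place {spec.n_wobbles} wobbles: only "
            f"{len(wobble_eligible)} G/U positions available"
        )
    wobbles = set(rng.choice(np.array(wobble_eligible), size=spec.n_wobbles,
                             replace=False)) if spec.n_wobbles else set()
    # 3'-pairing segment, target 5'->3' = descending miRNA positions
    seg = [(_WOBBLE_PARTNER if p in wobbles else _WC_PARTNER)[m[p - 1]]
           for p in reversed(covered)]
    if spec.bulge_nts:
        if k < 2:
            raise ValueError("a bulge needs at least two flanking pairs")
        cut = k // 2
        bulge = "".join(_inert_nt(rng, m, None, params)
                        for _ in range(spec.bulge_nts))
        seg = seg[:cut] + list(bulge) + seg[cut:]
    # spacer: offset more target nts than the unpaired miRNA nts 9..first-1
    spacer = "".join(_inert_nt(rng, m, None, params)
                     for _ in range(spec.offset))
    spacer += "".join(_inert_nt(rng, m, q, params)
                      for q in range(first - 1, 8, -1))
    seed_site = revcomp(m[1:8]) + "A"                 # 8mer
    body = "".join(seg) + spacer
    fill_len = params.window_len - len(body)
    if fill_len < 0:
        raise ValueError(
            f"trigger architecture ({len(body)} nt) exceeds the "
            f"{params.window_len}-nt search window"
        )
    # inert filler completes the window; the part in register with the
    # remaining miRNA 3' tail additionally avoids its wobble partners
    fill = ""
    for q in range(covered[-1] + 1, covered[-1] + 1 + fill_len):
        fill = _inert_nt(rng, m, q if q <= L else None, params) + fill
    upstream = fill + body
    intended = {
        "match_points": float(spec.n_scored_matches) * params.match_point,
        "end_bonus": params.end_bonus * sum(1 for p in covered
                                            if p in (L - 1, L - 2)),
        "wobble_end_bonus": 0.0,
        "gap_penalty": params.gap_penalty_per_nt * spec.bulge_nts,
        "mismatch_penalty": 0.0,
        "offset": spec.offset,
        "offset_penalty": params.offset_penalty_per_nt
        * max(0, spec.offset - params.offset_free),
    }
    intended["total"] = (intended["match_points"] + intended["end_bonus"]
                         + intended["wobble_end_bonus"]
                         - intended["gap_penalty"] - intended["mismatch_penalty"]
                         - intended["offset_penalty"])
    return upstream, seed_site, intended


def make_transcriptome(cfg: SimConfig,
                       mirnas: list[MiRNA] | None = None,
                       params: ScoringParams = ScoringParams(),
                       ) -> SimulatedTranscriptome:
    """Random regions with implanted decoy seed matches and trigger sites."""
    rng = np.random.default_rng(cfg.seed)
    if mirnas is None:
        mirnas = make_mirnas(cfg, rng)
    by_id = {m.mirna_id: m for m in mirnas}
    lengths = np.maximum(
        60, np.round(10 ** rng.normal(cfg.region_len_log10_mean,
                                      cfg.region_len_log10_sd,
                                      cfg.n_regions)).astype(int))
    seqs = [random_rna(rng, n, cfg.gc_content) for n in lengths]

    # assign host regions for triggers
    hosts: dict[int, list[TriggerSpec]] = {}
    free = list(range(cfg.n_regions))
    for spec in cfg.trigger_specs:
        h = spec.host_region
        if h is None:
            h = int(rng.choice(np.array([i for i in free if i not in hosts])))
        hosts.setdefault(h, []).append(spec)

    truth_rows = []
    for h, specs in hosts.items():
        for spec in specs:
            mirna = by_id[spec.mirna_id]
            upstream, seed_site, intended = build_trigger_site(mirna, spec,
                                                               rng, params)
            block = upstream + seed_site
            seq = seqs[h]
            if len(block) > len(seq):
                raise ValueError(
                    f"trigger of length {len(block)} does not fit host region "
                    f"of length {len(seq)}"
                )
            pos = int(rng.integers(len(block), len(seq) + 1))  # block end
            seq = seq[:pos - len(block)] + block + seq[pos:]
            seqs[h] = seq
            seed_start = pos - len(seed_site)
            truth_rows.append({
                "transcript_id": f"tx{h:04d}", "mirna_id": spec.mirna_id,
                "site_type": "8mer", "seed_start": seed_start,
                "seed_end": pos, **intended,
            })

    # decoy seed matches (seed-only, no 3' architecture)
    decoy_rows = []
    for i, seq in enumerate(seqs):
        if i in hosts:
            continue
        if rng.random() < cfg.decoy_seed_rate:
            mirna = mirnas[int(rng.integers(len(mirnas)))]
            site = revcomp(mirna.sequence[1:8]) + "A"
            pos = int(rng.integers(0, len(seq) - len(site) + 1))
            seqs[i] = seq[:pos] + site + seq[pos + len(site):]
            decoy_rows.append({"transcript_id": f"tx{i:04d}",
                               "mirna_id": mirna.mirna_id, "seed_start": pos})

    tpms = 10 ** rng.normal(cfg.tpm_log10_mean, cfg.tpm_log10_sd, cfg.n_regions)
    regions = [
        TranscriptRegion(transcript_id=f"tx{i:04d}", sequence=s,
                         gene_id=f"gene{i:04d}", tpm=float(tpms[i]))
        for i, s in enumerate(seqs)
    ]
    tpm_df = pd.DataFrame({
        "transcript_id": [r.transcript_id for r in regions],
        "gene_id": [r.gene_id for r in regions],
        "tpm": np.round(tpms, 4),
    })
    truth = pd.DataFrame(truth_rows)
    truth.attrs["decoys"] = pd.DataFrame(decoy_rows)
    return SimulatedTranscriptome(mirnas=mirnas, regions=regions, tpm=tpm_df,
                                  truth=truth)


# ---------------------------------------------------------------------------
# differential-expression table
# ---------------------------------------------------------------------------

def simulate_de_table(cfg: SimConfig,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Log2FC table with predicted targets shifted down by ``de_shift``.

    Nontargets: log2fc ~ Normal(0, de_noise).  Targets: Normal(-de_shift * w,
    de_noise) where w averages 1 and couples to the context-style score with
    strength ``context_effect`` (0 = flat shift).  UTR lengths and TPM are
    lognormal; the TPM draw leaves a tail below the 10-TPM floor so the
    expression filter is exercised.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    n_t = int(round(cfg.frac_targets * n))
    is_target = np.zeros(n, dtype=bool)
    is_target[:n_t] = True
    utr = np.maximum(30, np.round(
        10 ** rng.normal(cfg.utr_len_log10_mean, cfg.utr_len_log10_sd, n)
    ).astype(int))
    tpm = 10 ** rng.normal(cfg.de_tpm_log10_mean, cfg.de_tpm_log10_sd, n)
    context = np.full(n, np.nan)
    context[:n_t] = -np.abs(rng.normal(0.3, 0.15, n_t))
    w = np.ones(n)
    if cfg.context_effect and n_t > 1:
        z = (np.abs(context[:n_t]) - np.abs(context[:n_t]).mean())
        z /= max(np.abs(context[:n_t]).std(), 1e-12)
        w[:n_t] = np.maximum(0.0, 1.0 + cfg.context_effect * z)
    shift = np.where(is_target, -cfg.de_shift * w, 0.0)
    log2fc = rng.normal(shift, cfg.de_noise)
    return pd.DataFrame({
        "gene_id": [f"g{i:05d}" for i in range(n)],
        "log2fc": log2fc,
        "mean_tpm": tpm,
        "utr3_len": utr,
        "is_predicted_target": is_target,
        "context_score": context,
    })


# ---------------------------------------------------------------------------
# small-RNA reads and counts
# ---------------------------------------------------------------------------

def simulate_reads(mirnas: list[MiRNA], true_counts: dict[str, int],
                   rng: np.random.Generator,
                   len_jitter: int = 2) -> tuple[list[str], pd.Series]:
    """Reads drawn per the given per-miRNA counts, with 3'-end length jitter.

    Jitter trims or extends the 3' end by up to ``len_jitter`` nt but never
    touches the first 19 nt, so assignment-by-prefix recovers the drawn
    counts exactly.  Returns (reads, truth counts) with reads in a shuffled
    deterministic order.
    """
    by_id = {m.mirna_id: m for m in mirnas}
    reads: list[str] = []
    for mid, count in true_counts.items():
        seq = by_id[mid].sequence
        for _ in range(int(count)):
            j = int(rng.integers(-len_jitter, len_jitter + 1))
            if j >= 0:
                read = seq + random_rna(rng, j)
            else:
                read = seq[:max(19, len(seq) + j)]
            reads.append(read)
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]
    truth = pd.Series({mid: int(c) for mid, c in true_counts.items()},
                      dtype=int)
    return reads, truth


def simulate_clone_counts(cfg: SimConfig, rng: np.random.Generator,
                          n_wt: int = 4, n_mut: int = 4,
                          target_fold: float = 3.0,
                          base_target: float = 2e4,
                          base_normalizer: float = 4e4,
                          base_other: float = 9.4e5) -> MiRNACountMatrix:
    """Negative-binomial strand counts with shared clone production noise.

    Each clone draws a multiplicative production factor (lognormal, sigma =
    ln(clone_noise_factor)) applied to *both* hairpin strands - the shared
    variability that cotranscribed-strand normalisation must cancel.  In
    mutant clones (trigger loss) the target strand alone is elevated
    ``target_fold``-fold.
    """
    sigma = np.log(cfg.clone_noise_factor)
    r = cfg.nb_dispersion

    def nb(mean: float) -> int:
        mean = max(mean, 1e-9)
        return int(rng.negative_binomial(r, r / (r + mean)))

    rows, conditions = {}, {}
    for cond, n_cl, fold in (("WT", n_wt, 1.0), ("mutant", n_mut, target_fold)):
        for i in range(n_cl):
            sample = f"{cond}_{i + 1}"
            f = float(np.exp(rng.normal(0.0, sigma)))
            rows[sample] = pd.Series({
                "target-3p": nb(base_target * f * fold),
                "norm-5p": nb(base_normalizer * f),
                "other": nb(base_other),
            })
            conditions[sample] = cond
    return MiRNACountMatrix.from_samples(rows, conditions)


# ---------------------------------------------------------------------------
# species alignments
# ---------------------------------------------------------------------------

def simulate_species_alignment(cfg: SimConfig, site_region: str,
                               mirna: MiRNA, reference_site: SeedMatch,
                               rng: np.random.Generator | None = None,
                               hairpin_flank: int = 25,
                               ) -> tuple[SpeciesAlignment, dict[str, str]]:
    """Star-phylogeny divergence of a site region and its miRNA hairpin.

    Each species substitutes positions i.i.d. at ``substitution_rate`` on
    both the site region and the hairpin; optional deletions (``indel_rate``)
    are confined to non-seed positions.  The reference species ("ref") is
    returned unchanged.  Returns the alignment plus per-species genomic
    hairpin sequences.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    ref_hairpin = (random_rna(rng, hairpin_flank) + mirna.sequence
                   + random_rna(rng, hairpin_flank))
    seed_cols = set(range(reference_site.start, reference_site.end))

    def mutate(seq: str, protect: set[int] = frozenset(),
               allow_del: bool = False) -> str:
        out = []
        for i, ch in enumerate(seq):
            if allow_del and i not in protect and rng.random() < cfg.indel_rate:
                out.append("-")
                continue
            if rng.random() < cfg.substitution_rate:
                out.append(str(rng.choice(np.array([n for n in "ACGU"
                                                    if n != ch]))))
            else:
                out.append(ch)
        return "".join(out)

    rows = {"ref": site_region}
    hairpins = {"ref": ref_hairpin}
    for i in range(cfg.n_species):
        sp = f"sp{i + 1:02d}"
        rows[sp] = mutate(site_region, protect=seed_cols,
                          allow_del=cfg.indel_rate > 0)
        hairpins[sp] = mutate(ref_hairpin).replace("-", "")
    aln = SpeciesAlignment(rows=rows, reference_species="ref",
                           reference_site=reference_site)
    return aln, hairpins
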