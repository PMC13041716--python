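"""Independent brute-force oracles the implementation is checked against.

These apply the definitions directly - sliding-window site checks, exhaustive
enumeration of monotone pairing chains scored by literal rule application,
all-substrings Hamming search - and deliberately share no code with the
package's optimised routines.
"""

from triggerscan.io import revcomp

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def oracle_seed_matches(mirna_seq, region_seq, site_types):
    """Every-offset site check from the site-type definitions."""
    found = []
    n = len(region_seq)
    expected = {
        "6mer": revcomp(mirna_seq[1:7]),
        "7mer-m8": revcomp(mirna_seq[1:8]),
        "7mer-A1": revcomp(mirna_seq[1:7]) + "A",
        "8mer": revcomp(mirna_seq[1:8]) + "A",
    }
    priority = ["8mer", "7mer-m8", "7mer-A1", "6mer"]
    # core position s = start of the 6-nt segment pairing miRNA 2-7
    for s in range(n - 5):
        if region_seq[s:s + 6] != expected["6mer"]:
            continue
        for st in priority:
            seq = expected[st]
            start = s - 1 if st in ("8mer", "7mer-m8") else s
            if start < 0 or start + len(seq) > n:
                continue
            if region_seq[start:start + len(seq)] == seq and st in site_types:
                if "N" not in region_seq[start:start + len(seq)]:
                    found.append((st, start, start + len(seq)))
                break
    return sorted(found, key=lambda x: (x[1], x[2]))


def _rule_score(chain, mirna_seq, window_len, params):
    """Literal application of the five scoring rules to one pair chain."""
    L = len(mirna_seq)
    pts = 0.0
    for p, t, kind in chain:
        if kind == "WC" and p >= params.scored_from_position:
            pts += params.match_point                     # rule 1
        if p in (L - 1, L - 2):
            pts += params.end_bonus                       # rule 2
        if p == L and kind == "wobble":
            pts += params.wobble_end_bonus                # rule 3
    for (p1, t1, _), (p2, t2, _) in zip(chain, chain[1:]):
        a, b = p2 - p1 - 1, t1 - t2 - 1
        pts -= params.mismatch_penalty * min(a, b)        # rule 4 (mismatch)
        pts -= params.gap_penalty_per_nt * abs(a - b)     # rule 4 (gap)
    p0, t0, _ = chain[0]
    offset = (window_len - 1 - t0) - (p0 - 9)
    pts -= params.offset_penalty_per_nt * max(0, offset - params.offset_free)
    return pts


def oracle_best_pairing(mirna_seq, window, params):
    """Max score over exhaustive enumeration of all monotone pairing chains."""
    L = len(mirna_seq)
    W = len(window)
    cells = []
    for p in range(params.search_from_position, L + 1):
        for t in range(W):
            duo = (mirna_seq[p - 1], window[t])
            if duo in _WC:
                cells.append((p, t, "WC"))
            elif duo in _WOBBLE:
                cells.append((p, t, "wobble"))
    cells.sort(key=lambda c: (c[0], -c[1]))
    best = 0.0

    def rec(start, chain):
        nonlocal best
        if chain:
            s = _rule_score(chain, mirna_seq, W, params)
            if s > best:
                best = s
        for i in range(start, len(cells)):
            p, t, k = cells[i]
            if chain and (p <= chain[-1][0] or t >= chain[-1][1]):
                continue
            chain.append(cells[i])
            rec(i + 1, chain)
            chain.pop()

    rec(0, [])
    return best


def oracle_mature_match(reference, hairpin):
    """All-substrings Hamming scan: (best distance, leftmost best position)."""
    k = len(reference)
    best = None
    for s in range(len(hairpin) - k + 1):
        d = sum(a != b for a, b in zip(reference, hairpin[s:s + k]))
        if best is None or d < best[0]:
            best = (d, s)
    return best
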