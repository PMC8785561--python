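"""Independent brute-force oracles used to cross-check the pipeline.

Everything here is written straight-line from the definitions (plain
loops, math.log2, exhaustive enumeration) and deliberately shares no code
with the package beyond the amino-acid alphabet string constant.
"""

from __future__ import annotations

import itertools
import math

# BLOSUM62 marginals in the classic ARN... order, re-embedded independently
_ORACLE_BG_ORDER = "ARNDCQEGHILKMFPSTWYV"
_ORACLE_BG_VALUES = [
    0.078, 0.051, 0.041, 0.052, 0.024, 0.034, 0.059, 0.083, 0.025, 0.062,
    0.092, 0.056, 0.024, 0.044, 0.043, 0.059, 0.055, 0.014, 0.034, 0.072,
]
AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_background() -> dict[str, float]:
    total = sum(_ORACLE_BG_VALUES)
    raw = dict(zip(_ORACLE_BG_ORDER, _ORACLE_BG_VALUES))
    return {a: raw[a] / total for a in AA}


def oracle_weights(seqs: list[str]) -> list[float]:
    """Position-based (Henikoff) weights, plain loops."""
    n = len(seqs)
    raw = [0.0] * n
    for c in range(len(seqs[0])):
        col = [s[c] for s in seqs]
        residues = [ch for ch in col if ch in AA]
        if not residues:
            continue
        types = sorted(set(residues))
        r = len(types)
        for i, ch in enumerate(col):
            if ch in AA:
                raw[i] += 1.0 / (r * col.count(ch))
    raw = [x if x > 0 else 1.0 / n for x in raw]
    total = sum(raw)
    return [x / total for x in raw]


def oracle_jsd(p: list[float], q: list[float], lam: float = 0.5) -> float:
    r = [lam * pi + (1 - lam) * qi for pi, qi in zip(p, q)]

    def kl(a, b):
        return sum(ai * math.log2(ai / bi) for ai, bi in zip(a, b) if ai > 0)

    return lam * kl(p, r) + (1 - lam) * kl(q, r)


def oracle_track(
    seqs: list[str],
    lam: float = 0.5,
    window: int = 3,
    window_weight: float = 0.5,
    pseudocount: float = 1e-7,
    gap_penalty: bool = True,
    use_weights: bool = True,
) -> tuple[list[float], list[float]]:
    """(raw, windowed) JSD scores, straight-line re-implementation."""
    n = len(seqs)
    L = len(seqs[0])
    bg_map = oracle_background()
    bg = [bg_map[a] for a in AA]
    w = oracle_weights(seqs) if use_weights else [1.0 / n] * n
    raw = []
    for c in range(L):
        counts = {a: 0.0 for a in AA}
        gap = 0.0
        for i in range(n):
            ch = seqs[i][c]
            if ch == "-":
                gap += w[i]
            elif ch != "X":
                counts[ch] += w[i]
        vals = [counts[a] + pseudocount for a in AA]
        total = sum(vals)
        p = [v / total for v in vals] if total > 0 else [1.0 / 20] * 20
        score = oracle_jsd(p, bg, lam)
        if gap_penalty:
            score *= 1.0 - gap
        raw.append(score)
    windowed = []
    for c in range(L):
        neigh = [raw[j] for j in range(max(0, c - window), min(L, c + window + 1)) if j != c]
        if neigh and window > 0 and window_weight > 0:
            windowed.append(
                (1 - window_weight) * raw[c] + window_weight * sum(neigh) / len(neigh)
            )
        else:
            windowed.append(raw[c])
    return raw, windowed


def oracle_interchain_pairs(structure, cutoff: float = 5.0) -> set:
    """All inter-chain residue pairs with any heavy-atom pair <= cutoff,
    by exhaustive enumeration of atom pairs."""
    pairs = set()
    chains = structure.chains
    for ci, cj in itertools.combinations(range(len(chains)), 2):
        for res_a in chains[ci].residues:
            for res_b in chains[cj].residues:
                hit = any(
                    math.dist(a.coord, b.coord) <= cutoff
                    for a in res_a.atoms
                    for b in res_b.atoms
                    if a.element != "H" and b.element != "H"
                )
                if hit:
                    pairs.add(
                        (
                            chains[ci].chain_id, res_a.number,
                            chains[cj].chain_id, res_b.number,
                        )
                    )
    return pairs


def oracle_upgma(labels: list[str], dist: dict[frozenset, float]):
    """Brute-force UPGMA: returns merge heights.

    ``dist`` maps frozenset({a, b}) of leaf labels to distance.  Returns a
    list of (merged_leafsets, height) in merge order, where inter-cluster
    distance is the mean over all cross leaf pairs.
    """
    clusters: list[frozenset] = [frozenset([l]) for l in labels]
    merges = []

    def d(c1: frozenset, c2: frozenset) -> float:
        vals = [dist[frozenset([a, b])] for a in c1 for b in c2]
        return sum(vals) / len(vals)

    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            h = d(clusters[i], clusters[j])
            if best is None or h < best[0]:
                best = (h, i, j)
        h, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((merged, h))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def oracle_motif_hits(sequence: str, patterns: dict[str, str], region=None) -> set:
    """Exhaustive position-by-position wildcard matcher.

    Returns {(motif_name, 1-based start)} for occurrences fully inside
    ``region`` (1-based inclusive; default whole sequence).
    """
    if region is None:
        region = (1, len(sequence))
    lo, hi = region
    hits = set()
    for name, pat in patterns.items():
        for s in range(lo, hi - len(pat) + 2):
            window = sequence[s - 1 : s - 1 + len(pat)]
            if len(window) == len(pat) and all(
                pc == "x" or pc == wc for pc, wc in zip(pat, window)
            ):
                hits.add((name, s))
    return hits
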