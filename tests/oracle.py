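"""Independent brute-force oracles used by the tests.

Everything here is deliberately written with plain Python loops over the
public containers, independent of the vectorised production code paths it
cross-checks.
"""

from fractions import Fraction


def naive_skew_tf_gene(tensor, x, g, branch):
    """Mean difference over explicitly listed present species."""
    vals_m, vals_ms = [], []
    for s in tensor.species_ids:
        if not tensor.is_present(g, s):
            continue
        p = tensor.probability(x, g, s)
        if s in branch.M:
            vals_m.append(p)
        else:
            vals_ms.append(p)
    return sum(vals_m) / len(vals_m) - sum(vals_ms) / len(vals_ms)


def naive_team_skew(tensor, T, G, branch):
    pairs = [naive_skew_tf_gene(tensor, x, g, branch) for x in T for g in G]
    return sum(pairs) / len(pairs)


def naive_block_skew(tensor, T, T_star, G, branch):
    return naive_team_skew(tensor, T, G, branch) - naive_team_skew(tensor, T_star, G, branch)


def naive_improving_substitutions(tensor, module, block, decimals=8):
    """All strictly improving single-element substitutions of a block."""
    from tfrewire.skewness import usable_genes

    base = round(naive_block_skew(tensor, block.T, block.T_star, block.G, block.branch),
                 decimals)
    in_teams = set(block.T) | set(block.T_star)
    tf_candidates = [x for x in tensor.tf_ids if x not in in_teams]
    pool = usable_genes(tensor, block.branch, sorted(module.genes))
    gene_candidates = [g for g in pool if g not in set(block.G)]
    found = []
    for x in block.T:
        others = [t for t in block.T if t != x]
        for c in tf_candidates:
            s = round(naive_block_skew(tensor, others + [c], block.T_star,
                                       block.G, block.branch), decimals)
            if s > base:
                found.append(("T", x, c, s))
    for y in block.T_star:
        others = [t for t in block.T_star if t != y]
        for c in tf_candidates:
            s = round(naive_block_skew(tensor, block.T, others + [c],
                                       block.G, block.branch), decimals)
            if s > base:
                found.append(("T_star", y, c, s))
    for g in block.G:
        others = [h for h in block.G if h != g]
        for c in gene_candidates:
            s = round(naive_block_skew(tensor, block.T, block.T_star,
                                       others + [c], block.branch), decimals)
            if s > base:
                found.append(("G", g, c, s))
    return base, found


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_site_probability_fraction(counts, window, background, prior, pseudocount):
    """Exact-arithmetic posterior for one window (counts: list of 4-lists)."""
    order = "ACGT"
    like = Fraction(1)
    back = Fraction(1)
    for pos, ch in enumerate(window):
        row = [Fraction(c) + Fraction(pseudocount) for c in counts[pos]]
        total = sum(row)
        like *= row[order.index(ch)] / total
        back *= Fraction(background[order.index(ch)])
    p = Fraction(prior)
    return p * like / (p * like + (1 - p) * back)


def naive_occupancy(pwm, seq, background=(0.25, 0.25, 0.25, 0.25),
                    prior=1.0 / 600.0, pseudocount=0.5):
    """1 - prod(1 - q_w) over every window of both strands, plain loops."""
    width = pwm.width
    freqs = [[(pwm.counts[pos][b] + pseudocount)
              / (sum(pwm.counts[pos]) + 4 * pseudocount) for b in range(4)]
             for pos in range(width)]
    order = "ACGT"
    rc = "".join(_COMPLEMENT[c] for c in reversed(seq.upper()))
    no_bind = 1.0
    for strand in (seq.upper(), rc):
        for i in range(len(strand) - width + 1):
            window = strand[i:i + width]
            if any(ch not in order for ch in window):
                continue
            ratio = 1.0
            for pos, ch in enumerate(window):
                b = order.index(ch)
                ratio *= freqs[pos][b] / background[b]
            q = prior * ratio / (prior * ratio + (1.0 - prior))
            no_bind *= 1.0 - q
    return 1.0 - no_bind
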