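"""Independent brute-force oracles shared across test modules."""


def bruteforce_rss_gi(sg, og, si, oi):
    n_gc, n_i = len(og), len(oi)
    total = n_gc + n_i
    s = 0.0
    for a, b in zip(og, sg):
        s += n_i / total * (a - b) ** 2
    for a, b in zip(oi, si):
        s += n_gc / total * (a - b) ** 2
    return s


def bruteforce_rss_gig(pairs):
    counts = [len(o) for _, o in pairs]
    total = sum(counts)
    s = 0.0
    for (sim, obs), n_own in zip(pairs, counts):
        w = (total - n_own) / total
        for a, b in zip(obs, sim):
            s += w * (a - b) ** 2
    return s
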