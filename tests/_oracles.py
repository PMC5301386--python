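"""Independent brute-force reference implementations used by the tests.

Everything here is deliberately written with plain dictionaries and double
loops, sharing no code with the package, so agreement is meaningful.
"""

from __future__ import annotations

import math
from collections import Counter

AA = "ACDEFGHIKLMNPQRSTVWY"


def count_incidences(corpus, task: str, interval: int):
    """Dict-based window incidence counts: (singlets, pairs, states)."""
    states = ("E", "N") if task == "epitope" else ("E", "B")
    w = (interval - 1) // 2
    singles: Counter = Counter()
    pairs: Counter = Counter()
    for rec in corpus:
        lab = rec.labels if task == "epitope" else rec.exposure
        seq = rec.sequence
        for i, u in enumerate(lab):
            if u not in states or seq[i] not in AA:
                continue
            window = [
                j
                for j in range(i - w, i + w + 1)
                if 0 <= j < len(seq) and seq[j] in AA
            ]
            for j in window:
                singles[(u, seq[j])] += 1
            for a in range(len(window)):
                for b in range(a + 1, len(window)):
                    key = tuple(sorted((seq[window[a]], seq[window[b]])))
                    pairs[(u, key)] += 1
    return singles, pairs, states


def corrected_dw(n_u_s, n_u, n_s, total, sigma, rt):
    """-RT ln of the shrunk frequency ratio; 0 for unseen types."""
    if n_s == 0 or n_u == 0:
        return 0.0
    r = n_u_s * total / (n_u * n_s)
    return -rt * math.log((sigma + n_s * r) / (sigma + n_s))


def dw1_value(singles, u, s, sigma, rt):
    total = sum(singles.values())
    n_u = sum(v for (uu, _), v in singles.items() if uu == u)
    n_s = sum(v for (_, ss), v in singles.items() if ss == s)
    return corrected_dw(singles[(u, s)], n_u, n_s, total, sigma, rt)


def dw2_value(pairs, u, s, s2, sigma, rt):
    key = tuple(sorted((s, s2)))
    total = sum(pairs.values())
    n_u = sum(v for (uu, _), v in pairs.items() if uu == u)
    n_ss = sum(v for (_, kk), v in pairs.items() if kk == key)
    return corrected_dw(pairs[(u, key)], n_u, n_ss, total, sigma, rt)


def score(singles, pairs, sequence, i, u, interval, sigma, rt):
    """Brute-force (dW1, dW2) for one residue."""
    w = (interval - 1) // 2
    window = [
        j
        for j in range(i - w, i + w + 1)
        if 0 <= j < len(sequence) and sequence[j] in AA
    ]
    s1 = sum(dw1_value(singles, u, sequence[j], sigma, rt) for j in window)
    s2 = sum(
        dw2_value(pairs, u, sequence[window[a]], sequence[window[b]], sigma, rt)
        for a in range(len(window))
        for b in range(a + 1, len(window))
    )
    return s1, s2


def auc_pairwise(scores, labels):
    """O(n^2) Mann-Whitney AUC: concordant + half ties over all +/- pairs."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def ks_sup(a, b):
    """Brute-force sup |ECDF_a - ECDF_b| over all sample points."""
    best = 0.0
    for x in list(a) + list(b):
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        best = max(best, abs(fa - fb))
    return best


def random_toy_corpus(rng, n_records=4, length=30):
    """Random labeled corpus for oracle comparisons (no package code)."""
    from episeq.seqdata import AntigenRecord, Corpus

    records = []
    for i in range(n_records):
        seq = "".join(rng.choice(list(AA), size=length))
        labels = "".join(rng.choice(["E", "N"], size=length, p=[0.25, 0.75]))
        exposure = "".join(rng.choice(["E", "B"], size=length))
        records.append(
            AntigenRecord(
                id=f"r{i}", sequence=seq, labels=labels, exposure=exposure
            )
        )
    return Corpus(records)
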