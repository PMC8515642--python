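"""Independent brute-force oracles: plain-loop implementations of the
descriptor and metric formulas, kept deliberately separate from the package
code paths they are used to check."""

import math

from pcmaffinity._fixtures import AA_ORDER, normalize_scale


def moreau_broto_oracle(seq, scale, maxlag):
    p = normalize_scale(scale)
    vals = [p[c] for c in seq]
    out = []
    for d in range(1, maxlag + 1):
        total = 0.0
        for i in range(len(seq) - d):
            total += vals[i] * vals[i + d]
        out.append(total / (len(seq) - d))
    return out


def moran_oracle(seq, scale, maxlag):
    p = normalize_scale(scale)
    vals = [p[c] for c in seq]
    n = len(vals)
    mean = sum(vals) / n
    denom = sum((v - mean) ** 2 for v in vals) / n
    out = []
    for d in range(1, maxlag + 1):
        if denom == 0:
            out.append(0.0)
            continue
        num = sum((vals[i] - mean) * (vals[i + d] - mean) for i in range(n - d)) / (n - d)
        out.append(num / denom)
    return out


def geary_oracle(seq, scale, maxlag):
    p = normalize_scale(scale)
    vals = [p[c] for c in seq]
    n = len(vals)
    mean = sum(vals) / n
    denom = sum((v - mean) ** 2 for v in vals) / (n - 1)
    out = []
    for d in range(1, maxlag + 1):
        if denom == 0:
            out.append(0.0)
            continue
        num = sum((vals[i] - vals[i + d]) ** 2 for i in range(n - d)) / (2 * (n - d))
        out.append(num / denom)
    return out


def socn_oracle(seq, dmat, maxlag):
    out = []
    for d in range(1, maxlag + 1):
        out.append(sum(dmat.loc[seq[i], seq[i + d]] ** 2 for i in range(len(seq) - d)))
    return out


def qso_oracle(seq, dmat, maxlag, weight=0.1):
    n = len(seq)
    freqs = {aa: seq.count(aa) / n for aa in AA_ORDER}
    taus = socn_oracle(seq, dmat, maxlag)
    denom = sum(freqs.values()) + weight * sum(taus)
    residue_terms = [freqs[aa] / denom for aa in AA_ORDER]
    coupling_terms = [weight * t / denom for t in taus]
    return residue_terms + coupling_terms


def metrics_oracle(actual, predicted):
    n = len(actual)
    d = [a - p for a, p in zip(actual, predicted)]
    sse = sum(x * x for x in d)
    mse = sse / n
    rmse = math.sqrt(mse)
    mae = sum(abs(x) for x in d) / n
    mean = sum(actual) / n
    sst = sum((a - mean) ** 2 for a in actual)
    r2 = 1 - sse / sst if sst > 0 else float("nan")
    return sse, mse, rmse, mae, r2
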