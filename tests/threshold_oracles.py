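"""Independent, loop-based reference implementations of each thresholding
criterion, used to cross-check the vectorized package implementations.

Every oracle is a direct brute-force optimizer of the method's published
criterion over all candidate thresholds (or, for the procedural methods
Triangle / Intermodes / Moments, a from-scratch re-implementation of the
defining computation), written in plain Python loops with no code shared
with the package. Ties break toward the lowest threshold index.
"""

import math

EPS = 1e-12


def _norm(hist):
    total = float(sum(hist))
    return [h / total for h in hist]


def _candidates(p):
    out = []
    acc = 0.0
    for t in range(255):
        acc += p[t]
        if EPS < acc < 1 - EPS:
            out.append(t)
    return out


def _argbest(scores, maximize):
    best_v = None
    for _, v in scores:
        if v is None:
            continue
        if best_v is None or (v > best_v if maximize else v < best_v):
            best_v = v
    if best_v is None:
        return None
    # lowest index within a tiny tolerance of the optimum (criterion
    # plateaus over empty-bin runs are exact ties mathematically)
    tol = 1e-9 * max(1.0, abs(best_v))
    for t, v in scores:
        if v is not None and abs(v - best_v) <= tol:
            return t
    return None


def otsu(hist):
    p = _norm(hist)
    scores = []
    for t in _candidates(p):
        w0 = sum(p[: t + 1])
        w1 = 1.0 - w0
        mu0 = sum(g * p[g] for g in range(t + 1)) / w0
        mu1 = sum(g * p[g] for g in range(t + 1, 256)) / w1
        scores.append((t, w0 * w1 * (mu0 - mu1) ** 2))
    return _argbest(scores, maximize=True)


def huang(hist):
    p = _norm(hist)
    nz = [g for g in range(256) if p[g] > 0]
    first, last = nz[0], nz[-1]
    c = float(last - first)
    scores = []
    for t in _candidates(p):
        if not first <= t < last:
            continue
        w0 = sum(p[: t + 1])
        w1 = 1.0 - w0
        mu0 = sum(g * p[g] for g in range(t + 1)) / w0
        mu1 = sum(g * p[g] for g in range(t + 1, 256)) / w1
        ent = 0.0
        for g in range(256):
            mu = mu0 if g <= t else mu1
            u = 1.0 / (1.0 + abs(g - mu) / c)
            if 0 < u < 1:
                ent += p[g] * (-u * math.log(u) - (1 - u) * math.log(1 - u))
        scores.append((t, ent))
    return _argbest(scores, maximize=False)


def li(hist):
    p = _norm(hist)
    scores = []
    for t in _candidates(p):
        a0 = sum(g * p[g] for g in range(t + 1))
        a1 = sum(g * p[g] for g in range(t + 1, 256))
        w0 = sum(p[: t + 1])
        w1 = 1.0 - w0
        term0 = a0 * math.log(a0 / w0) if a0 > EPS else 0.0
        term1 = a1 * math.log(a1 / w1) if a1 > EPS else 0.0
        scores.append((t, -(term0 + term1)))
    return _argbest(scores, maximize=False)


def yen(hist):
    p = _norm(hist)
    scores = []
    for t in _candidates(p):
        p0 = sum(p[: t + 1])
        p1 = 1.0 - p0
        s0 = sum(v * v for v in p[: t + 1])
        s1 = sum(v * v for v in p[t + 1 :])
        crit = -math.log(max(s0, EPS) * max(s1, EPS)) + 2 * math.log(
            max(p0, EPS) * max(p1, EPS)
        )
        scores.append((t, crit))
    return _argbest(scores, maximize=True)


def renyi_entropy(hist, alpha=0.5):
    p = _norm(hist)
    scores = []
    for t in _candidates(p):
        w0 = sum(p[: t + 1])
        w1 = 1.0 - w0
        s0 = sum((v / w0) ** alpha for v in p[: t + 1] if v > 0)
        s1 = sum((v / w1) ** alpha for v in p[t + 1 :] if v > 0)
        crit = (math.log(s0) + math.log(s1)) / (1.0 - alpha)
        scores.append((t, crit))
    return _argbest(scores, maximize=True)


def max_entropy(hist):
    p = _norm(hist)
    scores = []
    for t in _candidates(p):
        w0 = sum(p[: t + 1])
        w1 = 1.0 - w0
        h0 = -sum((v / w0) * math.log(v / w0) for v in p[: t + 1] if v > 0)
        h1 = -sum((v / w1) * math.log(v / w1) for v in p[t + 1 :] if v > 0)
        scores.append((t, h0 + h1))
    return _argbest(scores, maximize=True)


def shanbhag(hist):
    p = _norm(hist)
    cum = []
    acc = 0.0
    for v in p:
        acc += v
        cum.append(acc)
    scores = []
    for t in _candidates(p):
        w0 = cum[t]
        w1 = 1.0 - w0
        term_b = 0.5 / w0
        ent_b = 0.0
        for g in range(1, t + 1):
            ent_b -= p[g] * math.log(1.0 - term_b * cum[g - 1])
        ent_b *= term_b
        term_f = 0.5 / w1
        ent_f = 0.0
        for g in range(t + 1, 255):
            above = 1.0 - cum[g]
            ent_f -= p[g] * math.log(1.0 - term_f * above)
        ent_f *= term_f
        scores.append((t, abs(ent_b - ent_f)))
    return _argbest(scores, maximize=False)


def moments(hist):
    p = _norm(hist)
    m1 = sum(g * p[g] for g in range(256))
    m2 = sum(g * g * p[g] for g in range(256))
    m3 = sum(g * g * g * p[g] for g in range(256))
    cd = m2 - m1 * m1
    if cd <= EPS:
        return None
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4 * c0, 0.0)
    z0 = 0.5 * (-c1 - math.sqrt(disc))
    z1 = 0.5 * (-c1 + math.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)
    acc = 0.0
    for t in range(256):
        acc += p[t]
        if acc >= p0 - EPS:
            return t
    return 254


def triangle(hist):
    nz = [g for g in range(256) if hist[g] > 0]
    first, last = nz[0], nz[-1]
    peak = max(range(256), key=lambda g: (hist[g], -g))
    right = (last - peak) >= (peak - first)
    end = last if right else first
    if end == peak:
        return (first + last) // 2
    lo, hi = (peak, end) if right else (end, peak)
    x1, y1 = float(peak), float(hist[peak])
    x2, y2 = float(end), float(hist[end])
    best_t, best_d = None, -1.0
    for g in range(lo, hi + 1):
        num = abs((y2 - y1) * (g - x1) - (x2 - x1) * (hist[g] - y1))
        if num > best_d:
            best_t, best_d = g, num
    return best_t


def intermodes(hist, max_iter=10_000):
    h = [float(v) for v in hist]
    for _ in range(max_iter):
        modes = []
        for k in range(256):
            left = h[k - 1] if k > 0 else 0.0
            right = h[k + 1] if k < 255 else 0.0
            if h[k] > left and h[k] > right:
                modes.append(k)
        if len(modes) == 2:
            return (modes[0] + modes[1]) // 2
        h = [
            ((h[k - 1] if k > 0 else 0.0) + h[k] + (h[k + 1] if k < 255 else 0.0)) / 3.0
            for k in range(256)
        ]
    return None


ORACLES = {
    "Otsu": otsu,
    "Huang": huang,
    "Li": li,
    "Yen": yen,
    "RenyiEntropy": renyi_entropy,
    "MaxEntropy": max_entropy,
    "Shanbhag": shanbhag,
    "Moments": moments,
    "Triangle": triangle,
    "Intermodes": intermodes,
}
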