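"""Independent brute-force oracles used by the test suite.

Deliberately naive: explicit Python loops and dictionary accumulation,
sharing no code with the package implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Co-occurrence
# ---------------------------------------------------------------------------

def glcm_matrix_brute(levels: np.ndarray, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized GLCM by enumerating every pixel pair."""
    rows, cols = levels.shape
    ng = int(levels.max())
    counts = np.zeros((ng, ng))
    dr, dc = offset
    for r in range(rows):
        for c in range(cols):
            a = levels[r, c]
            rr, cc = r + dr, c + dc
            if a > 0 and 0 <= rr < rows and 0 <= cc < cols:
                b = levels[rr, cc]
                if b > 0:
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    total = counts.sum()
    return counts / total if total else counts


def glcm_features_brute(P: np.ndarray, ng_image: int) -> dict[str, float]:
    """The 24 co-occurrence features via plain double loops."""
    ng = P.shape[0]
    px = {i: sum(P[i - 1, j - 1] for j in range(1, ng + 1))
          for i in range(1, ng + 1)}
    mu = sum(i * px[i] for i in px)
    sigma2 = sum((i - mu) ** 2 * px[i] for i in px)
    psum: dict[int, float] = {}
    pdiff: dict[int, float] = {}
    feats = dict.fromkeys((
        "Autocorrelation", "ClusterProminence", "ClusterShade",
        "ClusterTendency", "Contrast", "JointEnergy", "JointEntropy", "Idm",
        "Idmn", "Id", "Idn", "InverseVariance", "MaximumProbability"), 0.0)
    hxy1 = hxy2 = 0.0
    for i in range(1, ng + 1):
        for j in range(1, ng + 1):
            p = P[i - 1, j - 1]
            psum[i + j] = psum.get(i + j, 0.0) + p
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0.0) + p
            feats["Autocorrelation"] += i * j * p
            feats["ClusterProminence"] += (i + j - 2 * mu) ** 4 * p
            feats["ClusterShade"] += (i + j - 2 * mu) ** 3 * p
            feats["ClusterTendency"] += (i + j - 2 * mu) ** 2 * p
            feats["Contrast"] += (i - j) ** 2 * p
            feats["JointEnergy"] += p * p
            if p > 0:
                feats["JointEntropy"] -= p * math.log2(p)
            feats["Idm"] += p / (1 + (i - j) ** 2)
            feats["Idmn"] += p / (1 + ((i - j) / ng_image) ** 2)
            feats["Id"] += p / (1 + abs(i - j))
            feats["Idn"] += p / (1 + abs(i - j) / ng_image)
            if i != j:
                feats["InverseVariance"] += p / (i - j) ** 2
            feats["MaximumProbability"] = max(feats["MaximumProbability"], p)
            if px[i] * px[j] > 0:
                if p > 0:
                    hxy1 -= p * math.log2(px[i] * px[j])
                hxy2 -= px[i] * px[j] * math.log2(px[i] * px[j])
    feats["JointAverage"] = mu
    feats["SumSquares"] = sigma2
    feats["DifferenceAverage"] = sum(k * v for k, v in pdiff.items())
    feats["DifferenceEntropy"] = -sum(v * math.log2(v)
                                      for v in pdiff.values() if v > 0)
    da = feats["DifferenceAverage"]
    feats["DifferenceVariance"] = sum((k - da) ** 2 * v
                                      for k, v in pdiff.items())
    feats["SumAverage"] = sum(k * v for k, v in psum.items())
    feats["SumEntropy"] = -sum(v * math.log2(v)
                               for v in psum.values() if v > 0)
    hx = -sum(px[i] * math.log2(px[i]) for i in px if px[i] > 0)
    hxy = feats["JointEntropy"]
    present = [i for i in px if px[i] > 0]
    if len(present) > 1 and sigma2 > 0:
        feats["Correlation"] = (feats["Autocorrelation"] - mu * mu) / sigma2
    else:
        feats["Correlation"] = 1.0
    feats["Imc1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    feats["Imc2"] = (math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy))))
                     if len(present) > 1 else 0.0)
    if len(present) > 1:
        sub = [[sum(P[i - 1, k - 1] * P[j - 1, k - 1] / (px[i] * px[k])
                    for k in present)
                for j in present] for i in present]
        ev = sorted(np.real(np.linalg.eigvals(np.array(sub))), reverse=True)
        feats["MCC"] = math.sqrt(max(0.0, min(1.0, ev[1])))
    else:
        feats["MCC"] = 1.0
    return feats


def glcm_brute(levels: np.ndarray, ng_image: int,
               offsets=((0, 1), (-1, 1), (-1, 0), (-1, -1))) -> dict[str, float]:
    """Angle-averaged brute-force co-occurrence features."""
    per_angle = []
    for off in offsets:
        P = glcm_matrix_brute(levels, off)
        if P.sum() > 0:
            per_angle.append(glcm_features_brute(P, ng_image))
    return {k: float(np.mean([d[k] for d in per_angle])) for k in per_angle[0]}


# ---------------------------------------------------------------------------
# Run length
# ---------------------------------------------------------------------------

def _walk_runs(levels: np.ndarray, start: tuple[int, int],
               step: tuple[int, int]) -> list[tuple[int, int]]:
    """Runs (level, length) along one scan line, walking pixel by pixel."""
    rows, cols = levels.shape
    r, c = start
    runs = []
    cur, length = 0, 0
    while 0 <= r < rows and 0 <= c < cols:
        v = int(levels[r, c])
        if v == cur:
            length += 1
        else:
            if cur > 0:
                runs.append((cur, length))
            cur, length = v, 1
        r += step[0]
        c += step[1]
    if cur > 0:
        runs.append((cur, length))
    return runs


def glrlm_runs_brute(levels: np.ndarray,
                     offset: tuple[int, int]) -> list[tuple[int, int]]:
    """All runs in one direction, by explicit line walking."""
    rows, cols = levels.shape
    dr, dc = offset
    step = (abs(dr), dc if dr == 0 else (dc if dr > 0 else -dc))
    # normalize: walk in +row direction for non-horizontal scans
    if offset == (0, 1):
        starts = [(r, 0) for r in range(rows)]
        step = (0, 1)
    elif offset == (-1, 0):
        starts = [(0, c) for c in range(cols)]
        step = (1, 0)
    elif offset == (-1, 1):  # 45 deg; walk down-left from top and right edges
        starts = [(0, c) for c in range(cols)] + [(r, cols - 1)
                                                  for r in range(1, rows)]
        step = (1, -1)
    elif offset == (-1, -1):  # 135 deg; walk down-right
        starts = [(0, c) for c in range(cols)] + [(r, 0)
                                                  for r in range(1, rows)]
        step = (1, 1)
    else:
        raise ValueError(offset)
    runs = []
    for s in starts:
        runs += _walk_runs(levels, s, step)
    return runs


def glrlm_features_brute(runs: list[tuple[int, int]],
                         n_pixels: int) -> dict[str, float]:
    nr = len(runs)
    counts: dict[tuple[int, int], float] = {}
    for lv, ln in runs:
        counts[(lv, ln)] = counts.get((lv, ln), 0.0) + 1.0
    by_level: dict[int, float] = {}
    by_len: dict[int, float] = {}
    for (lv, ln), c in counts.items():
        by_level[lv] = by_level.get(lv, 0.0) + c
        by_len[ln] = by_len.get(ln, 0.0) + c
    mu_i = sum(lv * c for (lv, _), c in counts.items()) / nr
    mu_j = sum(ln * c for (_, ln), c in counts.items()) / nr
    f = {
        "ShortRunEmphasis": sum(c / ln**2 for (_, ln), c in counts.items()) / nr,
        "LongRunEmphasis": sum(c * ln**2 for (_, ln), c in counts.items()) / nr,
        "GrayLevelNonUniformity": sum(v**2 for v in by_level.values()) / nr,
        "GrayLevelNonUniformityNormalized":
            sum(v**2 for v in by_level.values()) / nr**2,
        "RunLengthNonUniformity": sum(v**2 for v in by_len.values()) / nr,
        "RunLengthNonUniformityNormalized":
            sum(v**2 for v in by_len.values()) / nr**2,
        "RunPercentage": nr / n_pixels,
        "GrayLevelVariance":
            sum((lv - mu_i) ** 2 * c for (lv, _), c in counts.items()) / nr,
        "RunVariance":
            sum((ln - mu_j) ** 2 * c for (_, ln), c in counts.items()) / nr,
        "RunEntropy": -sum((c / nr) * math.log2(c / nr)
                           for c in counts.values()),
        "LowGrayLevelRunEmphasis":
            sum(c / lv**2 for (lv, _), c in counts.items()) / nr,
        "HighGrayLevelRunEmphasis":
            sum(c * lv**2 for (lv, _), c in counts.items()) / nr,
        "ShortRunLowGrayLevelEmphasis":
            sum(c / (lv**2 * ln**2) for (lv, ln), c in counts.items()) / nr,
        "ShortRunHighGrayLevelEmphasis":
            sum(c * lv**2 / ln**2 for (lv, ln), c in counts.items()) / nr,
        "LongRunLowGrayLevelEmphasis":
            sum(c * ln**2 / lv**2 for (lv, ln), c in counts.items()) / nr,
        "LongRunHighGrayLevelEmphasis":
            sum(c * lv**2 * ln**2 for (lv, ln), c in counts.items()) / nr,
    }
    return f


def glrlm_brute(levels: np.ndarray, n_pixels: int,
                offsets=((0, 1), (-1, 1), (-1, 0), (-1, -1))) -> dict[str, float]:
    per_dir = [glrlm_features_brute(glrlm_runs_brute(levels, off), n_pixels)
               for off in offsets]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in per_dir[0]}


# ---------------------------------------------------------------------------
# ROC / cutoff / LASSO
# ---------------------------------------------------------------------------

def auc_brute(scores, labels) -> float:
    """AUC by counting every positive-negative pair (ties count 1/2)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def youden_brute(scores, labels) -> tuple[float, float]:
    """(best J, an optimal threshold) by scanning every observed value."""
    s = np.asarray(scores, float)
    y = np.asarray(labels).astype(bool)
    best_j = -np.inf
    best_thr = None
    cands = sorted(set(s))
    thresholds = [min(cands) - 1.0] + [
        (a + b) / 2 for a, b in zip(cands[:-1], cands[1:])] + [max(cands) + 1.0]
    for thr in thresholds:
        pred = s > thr
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        j = sens + spec - 1
        if j > best_j:
            best_j, best_thr = j, thr
    return best_j, best_thr


def kkt_violation(Xs: np.ndarray, y: np.ndarray, coef: np.ndarray,
                  intercept: float, lam: float) -> float:
    """Max violation of the L1-logistic subgradient conditions.

    Objective (1/n) sum log-loss + lam * ||beta||_1; at the optimum
    |g_j| <= lam for zero coefficients and g_j = -lam*sign(beta_j)
    otherwise, with the intercept gradient 0.
    """
    n = len(y)
    p = 1.0 / (1.0 + np.exp(-(Xs @ coef + intercept)))
    g = Xs.T @ (p - y) / n
    viol = abs(float((p - y).mean()))
    for j, b in enumerate(coef):
        if b != 0:
            viol = max(viol, abs(g[j] + lam * np.sign(b)))
        else:
            viol = max(viol, max(0.0, abs(g[j]) - lam))
    return viol
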