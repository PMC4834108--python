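"""Independent brute-force reference implementations used by the tests.

These deliberately favour explicit loops and generic solvers over the
vectorised/dual formulations used by the package, so agreement is a real
cross-check rather than a tautology.
"""

import numpy as np
from scipy.ndimage import correlate, gaussian_filter


def frst_bruteforce(y_map, radii, alpha=2.0):
    """Pixel-by-pixel voting implementation of the radial symmetry transform
    (bright symmetry, positively affected pixels only)."""
    y_map = np.asarray(y_map, float)
    h, w = y_map.shape
    gy, gx = np.gradient(y_map)
    total = np.zeros((h, w))
    for r in radii:
        orient = np.zeros((h, w))
        magim = np.zeros((h, w))
        for i in range(h):
            for j in range(w):
                m = np.hypot(gx[i, j], gy[i, j])
                if m <= 1e-12:
                    continue
                pi = i + int(round(gy[i, j] / m * r))
                pj = j + int(round(gx[i, j] / m * r))
                if not (0 <= pi < h and 0 <= pj < w):
                    continue  # votes leaving the frame are discarded
                orient[pi, pj] += 1.0
                magim[pi, pj] += m
        kappa = 8.0 if r == 1 else 9.9
        orient = np.minimum(orient, kappa)
        s = (orient / kappa) ** alpha * (magim / kappa)
        total += gaussian_filter(s, sigma=max(r / 4.0, 0.5))
    total /= len(radii)
    rng = total.max() - total.min()
    if rng == 0:
        return np.zeros_like(total)
    return (total - total.min()) / rng


def matched_filter_bruteforce(y_map, sigma, n_orientations=12):
    """Direct spatial correlation with explicitly built oriented kernels
    (mirror boundary, matching np.pad 'reflect'), unnormalised mean
    response."""
    y_map = np.asarray(y_map, float)
    resp = np.zeros_like(y_map)
    half = max(int(np.ceil(3.0 * sigma * np.sqrt(2.0))), 2)
    rng = np.arange(-half, half + 1)
    for k in range(n_orientations):
        th = np.deg2rad(180.0 * k / n_orientations)
        kern = np.zeros((len(rng), len(rng)))
        for a, yy in enumerate(rng):
            for b, xx in enumerate(rng):
                u = xx * np.sin(th) + yy * np.cos(th)
                v = -xx * np.cos(th) + yy * np.sin(th)
                if abs(v) <= 3.0 * sigma and abs(u) <= 3.0 * sigma:
                    kern[a, b] = -np.exp(-(u ** 2) / (2.0 * sigma ** 2))
        support = kern < 0
        kern[support] -= kern[support].mean()
        resp += correlate(y_map, kern, mode="mirror")
    return resp / n_orientations


def glcm_features_bruteforce(p):
    """The 20 co-occurrence statistics by naive double loops (log base 2)."""
    p = np.asarray(p, float)
    n = p.shape[0]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sd_x = np.sqrt(sum((i - mu_x) ** 2 * px[i] for i in range(n)))
    sd_y = np.sqrt(sum((j - mu_y) ** 2 * py[j] for j in range(n)))
    p_sum = np.zeros(2 * n - 1)
    p_diff = np.zeros(n)
    for i in range(n):
        for j in range(n):
            p_sum[i + j] += p[i, j]
            p_diff[abs(i - j)] += p[i, j]

    def ent(dist):
        return -sum(v * np.log2(v) for v in np.ravel(dist) if v > 0)

    acor = sum(i * j * p[i, j] for i in range(n) for j in range(n))
    con = sum((i - j) ** 2 * p[i, j] for i in range(n) for j in range(n))
    if sd_x > 0 and sd_y > 0:
        corr = sum((i - mu_x) * (j - mu_y) * p[i, j]
                   for i in range(n) for j in range(n)) / (sd_x * sd_y)
    else:
        corr = 0.0
    cprom = sum((i + j - mu_x - mu_y) ** 4 * p[i, j]
                for i in range(n) for j in range(n))
    cshade = sum((i + j - mu_x - mu_y) ** 3 * p[i, j]
                 for i in range(n) for j in range(n))
    diss = sum(abs(i - j) * p[i, j] for i in range(n) for j in range(n))
    energy = float((p ** 2).sum())
    entropy = ent(p)
    homo = sum(p[i, j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    maxp = float(p.max())
    sos = sum((i - mu_x) ** 2 * p[i, j] for i in range(n) for j in range(n))
    savg = sum(k * p_sum[k] for k in range(2 * n - 1))
    sent = ent(p_sum)
    svar = sum((k - savg) ** 2 * p_sum[k] for k in range(2 * n - 1))
    davg = sum(k * p_diff[k] for k in range(n))
    dvar = sum((k - davg) ** 2 * p_diff[k] for k in range(n))
    dent = ent(p_diff)
    hxy = entropy
    hxy1 = -sum(p[i, j] * np.log2(px[i] * py[j])
                for i in range(n) for j in range(n)
                if p[i, j] > 0 and px[i] * py[j] > 0)
    hxy2 = -sum(px[i] * py[j] * np.log2(px[i] * py[j])
                for i in range(n) for j in range(n) if px[i] * py[j] > 0)
    hx, hy = ent(px), ent(py)
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(1.0 - np.exp(-2.0 * np.log(2.0) * (hxy2 - hxy)), 0.0))
    idn = sum(p[i, j] / (1 + abs(i - j) / n) for i in range(n) for j in range(n))
    idmn = sum(p[i, j] / (1 + ((i - j) / n) ** 2)
               for i in range(n) for j in range(n))
    return np.array([acor, con, corr, cprom, cshade, diss, energy, entropy,
                     homo, maxp, sos, savg, svar, sent, dvar, dent, imc1,
                     imc2, idn, idmn])


def inpaint_bruteforce(channel, vessels, length=11):
    """Directional grey closing by explicit max/min over line footprints
    (symmetric / edge-repeating boundary, as grey morphology uses)."""
    channel = np.asarray(channel, float)
    h, w = channel.shape
    c = (length - 1) / 2.0
    pad = length
    padded = np.pad(channel, pad, mode="symmetric")
    best = np.full((h, w), -np.inf)
    for k in range(8):
        th = np.deg2rad(22.5 * k)
        offs = set()
        for t in np.linspace(-c, c, 4 * length):
            offs.add((int(np.clip(round(c + t * np.sin(th)), 0, length - 1)) -
                      int(c),
                      int(np.clip(round(c + t * np.cos(th)), 0, length - 1)) -
                      int(c)))
        offs = sorted(offs)
        # dilation then erosion with the same footprint; the boundary is
        # re-extended between the stages (erosion sees the dilated image)
        dil = np.full_like(padded, -np.inf)
        for dy, dx in offs:
            dil = np.maximum(dil, np.roll(np.roll(padded, -dy, 0), -dx, 1))
        dil_core = dil[pad:-pad, pad:-pad]
        repadded = np.pad(dil_core, pad, mode="symmetric")
        ero = np.full_like(repadded, np.inf)
        for dy, dx in offs:
            ero = np.minimum(ero, np.roll(np.roll(repadded, dy, 0), dx, 1))
        best = np.maximum(best, ero[pad:-pad, pad:-pad])
    out = channel.copy()
    out[np.asarray(vessels, bool)] = best[np.asarray(vessels, bool)]
    return out


def twin_plane_activeset(x_own, x_other, c, eps_own, eps_other, delta=1e-6):
    """Exact solution of one Twin SVM dual (box QP) by active-set
    enumeration; feasible only for a handful of constraint points."""
    g = np.column_stack([x_own, np.full(len(x_own), eps_own)])
    h = np.column_stack([x_other, np.full(len(x_other), eps_other)])
    gram = g.T @ g + delta * np.eye(g.shape[1])
    q_mat = h @ np.linalg.solve(gram, h.T)
    lin = np.full(len(x_other), eps_other)
    ub = c * eps_own
    n = len(lin)
    best = None
    import itertools

    for states in itertools.product((0, 1, 2), repeat=n):  # lo, free, hi
        alpha = np.zeros(n)
        free = [i for i, s in enumerate(states) if s == 1]
        hi = [i for i, s in enumerate(states) if s == 2]
        alpha[hi] = ub
        if free:
            a = q_mat[np.ix_(free, free)]
            b = lin[free] - q_mat[np.ix_(free, hi)] @ alpha[hi] if hi else lin[free]
            try:
                alpha[free] = np.linalg.solve(a, b)
            except np.linalg.LinAlgError:
                continue
        if np.any(alpha < -1e-9) or np.any(alpha > ub + 1e-9):
            continue
        grad = q_mat @ alpha - lin
        ok = all(
            (s == 1 and abs(grad[i]) < 1e-7)
            or (s == 0 and grad[i] >= -1e-7)
            or (s == 2 and grad[i] <= 1e-7)
            for i, s in enumerate(states)
        )
        if not ok:
            continue
        val = 0.5 * alpha @ q_mat @ alpha - lin @ alpha
        if best is None or val < best[0]:
            best = (val, alpha)
    assert best is not None, "active-set enumeration found no KKT point"
    u = -np.linalg.solve(gram, h.T @ best[1])
    return u[:-1], float(u[-1])
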