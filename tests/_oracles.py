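"""Independent, definition-literal oracle implementations.

Everything here is written as plain Python loops straight from the printed
definitions (flood fill, per-edge counting, explicit regression sums), on
purpose sharing no code path with the package, so the two routes can be
compared on small random maps.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# patches by explicit flood fill (8-connectivity)
# ---------------------------------------------------------------------------

def flood_fill_patches(codes: np.ndarray, nodata: int = 0):
    """List of (class, set-of-cells) patches under 8-neighbour connectivity."""
    n_rows, n_cols = codes.shape
    seen = set()
    patches = []
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            if (r0, c0) in seen or codes[r0, c0] == nodata:
                continue
            cls = codes[r0, c0]
            stack = [(r0, c0)]
            cells = set()
            seen.add((r0, c0))
            while stack:
                r, c = stack.pop()
                cells.add((r, c))
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if (0 <= rr < n_rows and 0 <= cc < n_cols
                                and (rr, cc) not in seen
                                and codes[rr, cc] == cls):
                            seen.add((rr, cc))
                            stack.append((rr, cc))
            patches.append((int(cls), cells))
    return patches


def patch_perimeter_cells(codes: np.ndarray, cells, nodata: int = 0) -> int:
    """Perimeter in cell-side units: sides facing another class, nodata or outside."""
    n_rows, n_cols = codes.shape
    cls = codes[next(iter(cells))]
    p = 0
    for r, c in cells:
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                p += 1
            elif codes[rr, cc] != cls:
                p += 1
    return p


# ---------------------------------------------------------------------------
# the 17 landscape indices from their printed formulas
# ---------------------------------------------------------------------------

def max_like_adjacencies(n_cells: int) -> int:
    n = int(math.isqrt(n_cells))
    m = n_cells - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def metrics_oracle(codes: np.ndarray, cell_size: float,
                   nodata: int = 0) -> dict[str, float]:
    nan = float("nan")
    n_rows, n_cols = codes.shape
    valid = [(r, c) for r in range(n_rows) for c in range(n_cols)
             if codes[r, c] != nodata]
    z = len(valid)
    if z == 0:
        raise ValueError("empty map")
    area = z * cell_size**2
    ta_ha = area / 1e4

    patches = flood_fill_patches(codes, nodata)
    a = [len(cells) * cell_size**2 for _, cells in patches]
    p = [patch_perimeter_cells(codes, cells, nodata) * cell_size
         for _, cells in patches]
    np_count = len(patches)

    classes = sorted({int(codes[r, c]) for r, c in valid})
    m = len(classes)
    counts = {i: sum(1 for r, c in valid if codes[r, c] == i) for i in classes}
    prop = {i: counts[i] / z for i in classes}

    # edges: internal unlike (once) + boundary (valid cell vs outside/nodata)
    internal_unlike = 0
    boundary = 0
    g = {i: {k: 0 for k in classes} for i in classes}   # double-count adjacency
    for r, c in valid:
        for rr, cc in ((r, c + 1), (r + 1, c)):         # each internal pair once
            if 0 <= rr < n_rows and 0 <= cc < n_cols and codes[rr, cc] != nodata:
                i, k = int(codes[r, c]), int(codes[rr, cc])
                g[i][k] += 1
                g[k][i] += 1
                if i != k:
                    internal_unlike += 1
        for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
            if not (0 <= rr < n_rows and 0 <= cc < n_cols) or codes[rr, cc] == nodata:
                boundary += 1
    total_edge = (internal_unlike + boundary) * cell_size

    out = {}
    out["TA"] = ta_ha
    out["NP"] = float(np_count)
    out["PD"] = np_count / ta_ha * 100.0
    out["LPI"] = max(a) / area * 100.0
    out["ED"] = total_edge / ta_ha
    out["LSI"] = 0.25 * total_edge / math.sqrt(area)
    out["SHAPE_MN"] = sum(0.25 * pi / math.sqrt(ai) for pi, ai in zip(p, a)) / np_count

    if np_count >= 2:
        x = [math.log(pi) for pi in p]
        y = [math.log(ai) for ai in a]
        n = np_count
        sxx = n * sum(xi * xi for xi in x) - sum(x) ** 2
        sxy = n * sum(xi * yi for xi, yi in zip(x, y)) - sum(x) * sum(y)
        out["PAFRAC"] = 2.0 * sxx / sxy if (sxx > 0 and sxy != 0) else nan
    else:
        out["PAFRAC"] = nan

    if m >= 2:
        acc = 0.0
        for i in classes:
            row = sum(g[i].values())
            if row == 0:
                continue
            for k in classes:
                q = prop[i] * g[i][k] / row
                if q > 0:
                    acc += q * math.log(q)
        out["CONTAG"] = (1.0 + acc / (2.0 * math.log(m))) * 100.0
    else:
        out["CONTAG"] = nan

    tot_adj = sum(g[i][k] for i in classes for k in classes)
    out["PLADJ"] = (100.0 * sum(g[i][i] for i in classes) / tot_adj
                    if tot_adj > 0 else nan)

    if m >= 3:
        e = {(i, k): g[i][k] / 2.0 for i in classes for k in classes if i < k}
        tot = sum(e.values())
        if tot > 0:
            acc = -sum(v / tot * math.log(v / tot) for v in e.values() if v > 0)
            out["IJI"] = acc / math.log(0.5 * m * (m - 1)) * 100.0
        else:
            out["IJI"] = nan
    else:
        out["IJI"] = nan

    if z > 1:
        p_faces = [pi / cell_size for pi in p]
        a_cells = [ai / cell_size**2 for ai in a]
        num = sum(p_faces)
        den = sum(pf * math.sqrt(ac) for pf, ac in zip(p_faces, a_cells))
        out["COHESION"] = (1.0 - num / den) / (1.0 - 1.0 / math.sqrt(z)) * 100.0
    else:
        out["COHESION"] = nan

    out["DIVISION"] = 1.0 - sum((ai / area) ** 2 for ai in a)
    out["SPLIT"] = area**2 / sum(ai**2 for ai in a)
    out["SHDI"] = -sum(prop[i] * math.log(prop[i]) for i in classes)
    out["SHEI"] = out["SHDI"] / math.log(m) if m > 1 else 0.0

    ai_acc = 0.0
    for i in classes:
        mx = max_like_adjacencies(counts[i])
        if mx > 0:
            ai_acc += prop[i] * (g[i][i] / 2.0) / mx
    out["AI"] = ai_acc * 100.0
    return out


# ---------------------------------------------------------------------------
# other small oracles
# ---------------------------------------------------------------------------

def majority_block_oracle(codes: np.ndarray, factor: int,
                          nodata: int = 0) -> np.ndarray:
    """Exhaustive per-block modal class for integer aggregation factors."""
    n_rows, n_cols = codes.shape[0] // factor, codes.shape[1] // factor
    out = np.zeros((n_rows, n_cols), dtype=np.int64)
    for br in range(n_rows):
        for bc in range(n_cols):
            block = codes[br * factor:(br + 1) * factor,
                          bc * factor:(bc + 1) * factor].ravel()
            n_nodata = int((block == nodata).sum())
            if 2 * n_nodata > block.size or n_nodata == block.size:
                out[br, bc] = nodata
                continue
            best, best_n = None, -1
            for cls in sorted(set(int(v) for v in block) - {nodata}):
                n = int((block == cls).sum())
                if n > best_n:        # ties keep the smallest code
                    best, best_n = cls, n
            out[br, bc] = best
    return out


def cv_oracle(series) -> float:
    x = list(map(float, series))
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / (n - 1))
    return sd / abs(mean) * 100.0


def ols_slope_oracle(y) -> float:
    """Closed-form least-squares slope against 0..T-1."""
    t = list(range(len(y)))
    n = len(y)
    tm = sum(t) / n
    ym = sum(y) / n
    return (sum((ti - tm) * (yi - ym) for ti, yi in zip(t, y))
            / sum((ti - tm) ** 2 for ti in t))


def pearson_oracle(x, y) -> float:
    n = len(x)
    xm, ym = sum(x) / n, sum(y) / n
    num = sum((a - xm) * (b - ym) for a, b in zip(x, y))
    den = math.sqrt(sum((a - xm) ** 2 for a in x) * sum((b - ym) ** 2 for b in y))
    return num / den


def transition_count_oracle(codes_a: np.ndarray, codes_b: np.ndarray,
                            nodata: int = 0) -> dict[tuple[int, int], int]:
    out: dict[tuple[int, int], int] = {}
    for r in range(codes_a.shape[0]):
        for c in range(codes_a.shape[1]):
            a, b = int(codes_a[r, c]), int(codes_b[r, c])
            if a != nodata and b != nodata:
                out[(a, b)] = out.get((a, b), 0) + 1
    return out
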