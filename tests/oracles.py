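"""Independent brute-force re-implementations used as test oracles.

Everything here is written with explicit Python loops and textbook formulas,
deliberately sharing no code path with the package: a disagreement between
an oracle and the library is a real finding, not a tautology.
"""

import math


def _mean(xs):
    return sum(xs) / len(xs)


def _sd(xs):
    m = _mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def naive_pairwise_sd_mean(rows: dict) -> dict:
    """{gene: mean over partners of SD(row_g - row_k)} — delta-Ct / geNorm M."""
    genes = list(rows)
    out = {}
    for g in genes:
        sds = []
        for k in genes:
            if k == g:
                continue
            diff = [a - b for a, b in zip(rows[g], rows[k])]
            sds.append(_sd(diff))
        out[g] = _mean(sds)
    return out


def naive_genorm_exclusion(rows: dict):
    """Stepwise exclusion order and final pair, ties dropping the
    lexicographically last gene."""
    panel = sorted(rows)
    excluded = []
    while len(panel) > 2:
        m = naive_pairwise_sd_mean({g: rows[g] for g in panel})
        worst_val = max(m.values())
        worst = max(g for g in panel if m[g] == worst_val)
        excluded.append(worst)
        panel.remove(worst)
    return excluded, tuple(sorted(panel))


def naive_v_series(rows: dict, ranking: list) -> dict:
    """Pairwise variation V_n for n = 2..k-1 on log2-quantity rows."""
    n_samples = len(rows[ranking[0]])
    out = {}
    for n in range(2, len(ranking)):
        d = []
        for j in range(n_samples):
            nf_n = _mean([rows[g][j] for g in ranking[:n]])
            nf_n1 = _mean([rows[g][j] for g in ranking[: n + 1]])
            d.append(nf_n - nf_n1)
        out[n] = _sd(d)
    return out


def naive_bestkeeper(rows: dict) -> dict:
    """Per-gene BestKeeper descriptive stats and index correlation."""
    genes = list(rows)
    n = len(rows[genes[0]])
    index = []
    for j in range(n):
        index.append(math.exp(_mean([math.log(rows[g][j]) for g in genes])))
    out = {}
    for g in genes:
        xs = rows[g]
        am = _mean(xs)
        mad = _mean([abs(x - am) for x in xs])
        gm = math.exp(_mean([math.log(x) for x in xs]))
        r = _pearson(xs, index)
        out[g] = {
            "geo_mean": gm,
            "arith_mean": am,
            "min_ct": min(xs),
            "max_ct": max(xs),
            "sd": mad,
            "cv_pct": 100.0 * mad / am,
            "r": r,
        }
    out["_index"] = index
    return out


def _pearson(xs, ys):
    mx, my = _mean(xs), _mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(
        sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys)
    )
    return num / den


def naive_normfinder_ungrouped(rows: dict) -> dict:
    """Bias-corrected intragroup SD per gene, no group structure."""
    genes = list(rows)
    k = len(genes)
    n = len(rows[genes[0]])
    z = {}
    for g in genes:
        z[g] = [
            rows[g][j] - _mean([rows[h][j] for h in genes]) for j in range(n)
        ]
    s2 = {g: _sd(z[g]) ** 2 for g in genes}
    S = (k / (k - 1)) * sum(s2.values())
    out = {}
    for g in genes:
        sigma2 = (s2[g] - S / k**2) / (1 - 2 / k)
        out[g] = math.sqrt(max(sigma2, 0.0))
    return out


def naive_normfinder_grouped(rows: dict, groups: list) -> dict:
    """Grouped NormFinder rho per gene.

    *groups* is a per-sample list of labels aligned with the rows.
    """
    genes = list(rows)
    k = len(genes)
    n = len(groups)
    labels = []
    for g in groups:
        if g not in labels:
            labels.append(g)
    z = {
        g: [rows[g][j] - _mean([rows[h][j] for h in genes]) for j in range(n)]
        for g in genes
    }
    sigma2 = {}
    d = {}
    for lab in labels:
        idx = [j for j in range(n) if groups[j] == lab]
        s2 = {g: _sd([z[g][j] for j in idx]) ** 2 for g in genes}
        S = (k / (k - 1)) * sum(s2.values())
        for g in genes:
            sigma2[(g, lab)] = max((s2[g] - S / k**2) / (1 - 2 / k), 0.0)
            d[(g, lab)] = _mean([z[g][j] for j in idx])
    sizes = {lab: sum(1 for g in groups if g == lab) for lab in labels}
    out = {}
    for g in genes:
        dbar = _mean([d[(g, lab)] for lab in labels])
        dvar = sum((d[(g, lab)] - dbar) ** 2 for lab in labels) / (len(labels) - 1)
        noise = _mean([sigma2[(g, lab)] / sizes[lab] for lab in labels])
        gamma2 = max(dvar - noise, 0.0)
        terms = []
        for lab in labels:
            se2 = sigma2[(g, lab)] / sizes[lab]
            denom = gamma2 + se2
            shrunk = 0.0 if denom == 0 else (d[(g, lab)] - dbar) * gamma2 / denom
            terms.append(abs(shrunk) + math.sqrt(se2))
        out[g] = _mean(terms)
    return out


def naive_competition_rank(values: dict) -> dict:
    """1 + number of strictly smaller values."""
    return {
        g: 1 + sum(1 for h in values if values[h] < values[g]) for g in values
    }


def naive_geometric_mean(xs):
    return math.exp(_mean([math.log(x) for x in xs]))
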