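"""Spearman rank analyses linking kinetics to monomer conformation.

Rows of the observation table are (variant, ionic strength) conditions
carrying the fitted kinetic parameters (λ, κ, percent insoluble) and
the simulation-derived shape metrics (asphericity Δ, prolateness S,
Flory exponent ν).  Correlations are reported pooled across variants
and per variant, with a Simpson's-paradox check flagging pooled signs
that the within-variant correlations contradict.  A per-residue-pair
analysis correlates trajectory-averaged Cα–Cα distances with κ over
the canonical pairs common to all variants (splice-aware masking from
the sequences module); all residue numbering is canonical (1–140).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

KINETIC_COLUMNS = ["lam", "kap", "pct_insoluble"]
METRIC_COLUMNS = ["delta", "S", "nu"]


def spearman(x, y) -> float:
    """Spearman ρ with average-rank tie handling; NaN (flagged) if a
    vector is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined")
        return float("nan")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def validate_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"variant", "I_mM", *KINETIC_COLUMNS, *METRIC_COLUMNS}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"observation table lacks columns {sorted(missing)}")
    if table.duplicated(["variant", "I_mM"]).any():
        raise ValueError("duplicate (variant, ionic strength) rows")
    return table


@dataclass
class CorrelationMap:
    pooled: pd.DataFrame                 # kinetic × metric ρ matrix
    per_variant: dict[str, pd.DataFrame]
    n: pd.DataFrame                      # pairwise-complete observation counts


def metric_kinetics_heatmap(table: pd.DataFrame) -> CorrelationMap:
    """3×3 Spearman ρ between {λ, κ, insoluble} and {Δ, S, ν}.

    Pooled across variants, with per-variant matrices alongside; rows
    with a missing member of a pair are dropped pairwise (counts in
    ``n``).
    """
    table = validate_table(table)

    def _matrix(df: pd.DataFrame):
        rho = pd.DataFrame(index=KINETIC_COLUMNS, columns=METRIC_COLUMNS,
                           dtype=float)
        n = rho.copy()
        for kin in KINETIC_COLUMNS:
            for met in METRIC_COLUMNS:
                sub = df[[kin, met]].dropna()
                n.loc[kin, met] = len(sub)
                if len(sub) >= 3:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        rho.loc[kin, met] = spearman(sub[kin], sub[met])
        return rho, n

    pooled, n = _matrix(table)
    per_variant = {v: _matrix(g)[0] for v, g in table.groupby("variant")}
    return CorrelationMap(pooled, per_variant, n)


def simpson_check(table: pd.DataFrame, pair: tuple[str, str]) -> dict:
    """Compare the pooled ρ sign for (metric, kinetic) with per-variant signs.

    Raises the flag when the pooled sign disagrees with the majority of
    within-variant signs — the classic aggregation (Simpson's) paradox.
    With a single variant the flag is undefined.
    """
    met, kin = pair
    table = validate_table(table)
    sub = table[[kin, met, "variant"]].dropna()
    pooled = spearman(sub[kin], sub[met])
    per = {}
    for v, g in sub.groupby("variant"):
        if len(g) >= 3:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per[v] = spearman(g[kin], g[met])
    report = {"pair": pair, "pooled_rho": pooled, "per_variant_rho": per}
    signs = [np.sign(r) for r in per.values() if np.isfinite(r) and r != 0]
    if len(per) < 2:
        report["flag"] = None
        report["note"] = "fewer than 2 variants: paradox check undefined"
        return report
    majority = np.sign(sum(signs)) if signs else 0.0
    report["flag"] = bool(np.isfinite(pooled) and majority != 0
                          and np.sign(pooled) != majority)
    return report


def per_pair_correlation(table: pd.DataFrame, distances: pd.DataFrame,
                         mask: set[tuple[int, int]],
                         kinetic: str = "kap",
                         statistic: str = "mean") -> pd.DataFrame:
    """Spearman ρ between per-pair average Cα–Cα distance and a kinetic rate.

    ``distances`` is long-format (variant, I_mM, i, j, mean_d_nm) with i, j
    canonical 1-based residue numbers; every unmasked pair must be present
    for every (variant, I) row of ``table``.  Returns one row per unmasked
    pair with ρ and the observation count.
    """
    table = validate_table(table)
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    need = {"variant", "I_mM", "i", "j", "mean_d_nm"}
    if need - set(distances.columns):
        raise ValueError(f"distance table lacks columns {sorted(need - set(distances.columns))}")
    obs = table.dropna(subset=[kinetic])[["variant", "I_mM", kinetic]]
    merged = obs.merge(distances, on=["variant", "I_mM"], how="left")
    present = set(map(tuple, merged[["i", "j"]].dropna().astype(int)
                      .drop_duplicates().itertuples(index=False)))
    extra = present - mask
    if extra:
        raise ValueError(f"{len(extra)} distance pairs outside the common-pair "
                         "mask (should already be masked upstream)")
    rows = []
    n_obs = len(obs)
    for (i, j), grp in merged.groupby(["i", "j"]):
        if len(grp) != n_obs or grp.mean_d_nm.isna().any():
            raise ValueError(f"pair ({i}, {j}) missing for some conditions")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rho = spearman(grp.mean_d_nm, grp[kinetic])
        rows.append({"i": int(i), "j": int(j), "rho": rho, "n": len(grp)})
    out = pd.DataFrame(rows)
    missing = mask - set(map(tuple, out[["i", "j"]].itertuples(index=False)))
    if missing:
        raise ValueError(f"{len(missing)} masked-in pairs absent from the "
                         "distance table")
    return out.sort_values(["i", "j"]).reset_index(drop=True)


def top_pairs(per_pair: pd.DataFrame, k: int = 5) -> dict:
    """Most positively and most negatively κ-correlated residue pairs."""
    srt = per_pair.sort_values("rho")
    fmt = lambda df: [{"i": int(r.i), "j": int(r.j), "rho": float(r.rho)}
                      for r in df.itertuples()]
    return {"most_positive": fmt(srt.tail(k).iloc[::-1]),
            "most_negative": fmt(srt.head(k))}


def benjamini_hochberg(per_pair: pd.DataFrame) -> pd.DataFrame:
    """Optional BH-adjusted p-values for the per-pair map (off by default
    in reports; the headline analysis reports ρ only)."""
    n = per_pair["n"].to_numpy()
    rho = per_pair["rho"].to_numpy()
    # t-approximation for Spearman under H0
    t = rho * np.sqrt((n - 2) / np.clip(1 - rho**2, 1e-12, None))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    order = np.argsort(p)
    q = np.empty_like(p)
    m = len(p)
    prev = 1.0
    for rank, idx in enumerate(order[::-1]):
        prev = min(prev, p[idx] * m / (m - rank))
        q[idx] = prev
    out = per_pair.copy()
    out["p"] = p
    out["q_bh"] = q
    return out
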