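"""Ionic-strength bookkeeping and Debye–Hückel-motivated models for κ(I).

Two single-process models describe how the secondary-pathway rate κ
responds to the total ionic strength I of the buffer:

* "Free Energy Barrier" (FEB): ions screen an unfavourable electrostatic
  component of the barrier to templated conversion, so κ saturates,

      κ(I) = κ_sat · (κ0/κ_sat)^(2^(−I/I_mid));

* "Brønsted–Bjerrum" (BB): ions stabilise a pre-nucleation intermediate,
  giving unbounded exponential growth,

      κ(I) = κ0 · 2^(I/I2),

  where I2 is the ionic strength of two-fold enhancement.

Model selection uses the corrected Akaike criterion for Gaussian
residuals, AICc = n·ln(RSS/n) + 2p + 2p(p+1)/(n−p−1).  Under the FEB
picture the barrier splits as ΔG‡ = ΔG‡_charged + ΔG‡_noncharged, and
the saturated rates compare the non-electrostatic components between
two variants: ΔΔG‡_noncharged = −ln(κ_sat,a / κ_sat,b) in RT units.

Buffer recipes are reduced to ionic strength with phosphate speciated
by Henderson–Hasselbalch on pKa2 = 7.0 and Na⁺ set by electroneutrality;
20 mM sodium phosphate at pH 7.4 comes to 49 mM (nearest mM).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

PHOSPHATE_PKA2 = 7.0


@dataclass(frozen=True)
class BufferSpecies:
    name: str
    conc_mM: float


@dataclass(frozen=True)
class BufferRecipe:
    species: tuple[BufferSpecies, ...]
    pH: float = 7.4

    @classmethod
    def make(cls, pH: float = 7.4, **conc_mM: float) -> "BufferRecipe":
        """e.g. ``BufferRecipe.make(pH=7.4, sodium_phosphate=20, NaCl=100)``."""
        return cls(tuple(BufferSpecies(k, v) for k, v in conc_mM.items()), pH)


@dataclass
class SaltResponseFit:
    model: str                    # "free_energy_barrier" | "bronsted_bjerrum"
    kappa0: float
    kappa_sat: float | None       # FEB only
    I_mid: float | None           # FEB only, mM
    I_2: float | None             # BB only, mM
    rss: float
    aicc: float
    n_points: int
    dg_charged: float | None      # ln(kappa_sat/kappa0), RT units (FEB)
    converged: bool = True
    flags: tuple[str, ...] = ()


# ------------------------------------------------------------ ionic strength

#: Fully dissociating species: {ion charge: stoichiometry}.
_SIMPLE_SALTS = {
    "NaCl": {+1: 1, -1: 1},
    "KCl": {+1: 1, -1: 1},
}
#: Phosphate salts: (phosphate stoichiometry, fixed counter-cations).
_PHOSPHATE_SALTS = {
    "sodium_phosphate": (1, 0.0),   # counterion set purely by electroneutrality
    "Na2HPO4": (1, 2.0),
    "KH2PO4": (1, 1.0),
    "NaH2PO4": (1, 1.0),
    "K2HPO4": (1, 2.0),
}


def phosphate_fractions(pH: float, pka2: float = PHOSPHATE_PKA2
                        ) -> tuple[float, float]:
    """(H2PO4⁻, HPO4²⁻) fractions from Henderson–Hasselbalch on pKa2."""
    f2 = 1.0 / (1.0 + 10.0 ** (pka2 - pH))
    return 1.0 - f2, f2


def ionic_strength(recipe: BufferRecipe) -> float:
    """Total ionic strength I = ½·Σ cᵢzᵢ² in mM after speciation.

    Phosphate is split between H2PO4⁻ and HPO4²⁻ at the recipe pH; any
    charge not balanced by the fixed cations of the named salts is
    assigned to Na⁺ (electroneutrality).
    """
    if not 5.0 <= recipe.pH <= 9.0:
        warnings.warn("pH outside [5, 9]: phosphate speciation model is only "
                      "reliable near neutral pH")
    phosphate_total = 0.0
    cations = 0.0       # total positive charge from fixed salt cations, mM·e
    i_contrib = 0.0     # Σ c z² from fully dissociating salts
    for sp in recipe.species:
        if sp.conc_mM < 0:
            raise ValueError(f"negative concentration for {sp.name}")
        if sp.name in _SIMPLE_SALTS:
            for z, nu in _SIMPLE_SALTS[sp.name].items():
                i_contrib += nu * sp.conc_mM * z * z
        elif sp.name in _PHOSPHATE_SALTS:
            nu_p, n_cat = _PHOSPHATE_SALTS[sp.name]
            phosphate_total += nu_p * sp.conc_mM
            cations += n_cat * sp.conc_mM
        else:
            raise ValueError(f"unknown buffer species {sp.name!r}")
    f1, f2 = phosphate_fractions(recipe.pH)
    h2po4 = f1 * phosphate_total
    hpo4 = f2 * phosphate_total
    anion_charge = h2po4 + 2.0 * hpo4
    balancing_na = anion_charge - cations   # may be negative (excess cations)
    i_contrib += h2po4 * 1 + hpo4 * 4 + cations * 1 + balancing_na * 1
    return 0.5 * i_contrib


def equivalent_nacl(recipe: BufferRecipe, base: BufferRecipe) -> float:
    """NaCl concentration whose ionic strength matches I(recipe) − I(base)."""
    return ionic_strength(recipe) - ionic_strength(base)


# ------------------------------------------------------------ models


def feb_model(I, kappa0, kappa_sat, I_mid):
    """κ(I) = κ_sat·(κ0/κ_sat)^(2^(−I/I_mid)): κ0 at I=0, saturating at κ_sat."""
    I = np.asarray(I, float)
    return kappa_sat * (kappa0 / kappa_sat) ** (2.0 ** (-I / I_mid))


def bb_model(I, kappa0, I_2):
    """κ(I) = κ0·2^(I/I2): unbounded exponential enhancement."""
    I = np.asarray(I, float)
    return kappa0 * 2.0 ** (I / I_2)


def aicc(rss: float, n: int, p: int) -> float:
    """Corrected Akaike criterion for Gaussian residuals."""
    if n <= p + 1:
        raise ValueError("AICc undefined: need n > p + 1")
    if rss <= 0:
        rss = np.finfo(float).tiny
    return n * math.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def fit_salt_response(points, model: str = "free_energy_barrier"
                      ) -> SaltResponseFit:
    """Levenberg–Marquardt least-squares fit of κ(I) for one model.

    ``points`` is a sequence of (I in mM, κ in h⁻¹).
    """
    pts = np.asarray(list(points), float)
    I, kap = pts[:, 0], pts[:, 1]
    if np.any(kap <= 0):
        raise ValueError("κ values must be positive")
    flags: list[str] = []
    if model in ("free_energy_barrier", "feb"):
        p = 3
        if len(I) < p + 2:
            raise ValueError("need at least 5 points for a FEB fit with AICc")
        k0 = max(kap[np.argmin(I)], 1e-12)
        ksat = max(kap.max(), k0 * 1.001)
        p0 = [k0, ksat, float(np.median(I))]
        try:
            popt, _ = curve_fit(feb_model, I, kap, p0=p0, method="lm",
                                maxfev=20000)
            converged = True
        except RuntimeError:
            popt, converged = p0, False
            flags.append("non-convergence")
        k0, ksat, imid = (float(v) for v in popt)
        rss = float(np.sum((feb_model(I, *popt) - kap) ** 2))
        if abs(ksat - k0) < 1e-6 * max(abs(ksat), 1e-12):
            flags.append("I_mid unidentifiable: flat response")
        return SaltResponseFit("free_energy_barrier", k0, ksat, imid, None,
                               rss, aicc(rss, len(I), p), len(I),
                               math.log(ksat / k0) if k0 > 0 and ksat > 0 else None,
                               converged, tuple(flags))
    if model in ("bronsted_bjerrum", "bb"):
        p = 2
        if len(I) < p + 2:
            raise ValueError("need at least 4 points for a BB fit with AICc")
        slope = np.polyfit(I, np.log2(kap), 1)[0]
        i2 = 1.0 / slope if slope > 0 else float(np.max(I))
        p0 = [max(kap[np.argmin(I)], 1e-12), i2]
        try:
            popt, _ = curve_fit(bb_model, I, kap, p0=p0, method="lm",
                                maxfev=20000)
            converged = True
        except RuntimeError:
            popt, converged = p0, False
            flags.append("non-convergence")
        rss = float(np.sum((bb_model(I, *popt) - kap) ** 2))
        return SaltResponseFit("bronsted_bjerrum", float(popt[0]), None, None,
                               float(popt[1]), rss, aicc(rss, len(I), p),
                               len(I), None, converged, tuple(flags))
    raise ValueError(f"unknown model {model!r}")


def compare_models(points) -> dict:
    """Fit both κ(I) models and report ΔAICc (FEB − BB)."""
    feb = fit_salt_response(points, "free_energy_barrier")
    bb = fit_salt_response(points, "bronsted_bjerrum")
    return {"feb": feb, "bb": bb, "delta_aicc_feb_minus_bb": feb.aicc - bb.aicc,
            "preferred": "free_energy_barrier" if feb.aicc < bb.aicc
            else "bronsted_bjerrum"}


def ddg_noncharged(kappa_sat_a: float, kappa_sat_b: float) -> float:
    """ΔΔG‡_noncharged (a vs b) = −ln(κ_sat,a/κ_sat,b), RT units.

    Assumes a common Arrhenius prefactor between the variants, so the
    fully screened (saturated) rates compare the non-electrostatic
    barrier components directly.
    """
    if kappa_sat_a <= 0 or kappa_sat_b <= 0:
        raise ValueError("saturated rates must be positive")
    return -math.log(kappa_sat_a / kappa_sat_b)
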