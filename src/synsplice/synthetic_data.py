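"""Ground-truth synthetic generators for every input class of the pipeline.

Each generator draws from the forward model the corresponding fitter
assumes — sigmoidal ThT curves from the empirical growth equation
(optionally with plateau-phase flocculation decay), κ(I) series from
either ionic-strength model, seeded-growth exponentials with or without
a fragmentation aging effect, Gaussian-chain and tethered-compact toy
ensembles, Gaussian Taylorgrams, and planted-signal observation tables
— and returns the data together with the truth parameters, so every
stage of the pipeline can be regression-tested without external data.

Noise defaults (σ = 0.01–0.05 normalised units for fluorescence traces)
emulate typical plate-reader variability.  All generators are
deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .tht_kinetics import ThTTrace, amyloid_curve
from .salt_models import feb_model, bb_model
from .frag_test import seeded_curve
from .fida import Taylorgram, expected_sigma_t2

DEFAULT_I_GRID_MM = (49.0, 99.0, 149.0, 199.0, 249.0, 449.0)


# ------------------------------------------------------------ ThT curves


def gen_tht(lam: float, kap: float, theta: float, t_grid,
            noise_sigma: float = 0.02, flocculation_rate: float | None = None,
            seed: int = 0, well_id: str = "synthetic",
            condition: dict | None = None) -> tuple[ThTTrace, dict]:
    """Sigmoidal ThT trace from the empirical growth model plus noise.

    ``flocculation_rate`` (h⁻¹), when given, applies a first-order decay
    to the plateau so the trace maximum occurs before the final time
    point, exercising the truncation-at-maximum fitting rule.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(t_grid, float)
    y = amyloid_curve(t, lam, kap, theta)
    if flocculation_rate is not None:
        # first-order loss of plateau signal, acting once growth is complete
        # so the pre-maximum (fitted) portion of the curve is untouched
        t_plateau = (t[np.argmax(y >= 0.99 * y.max())] if y.max() > 0
                     else t[-1])
        decay = np.exp(-flocculation_rate * np.clip(t - t_plateau, 0, None))
        y = y * decay
    y = y + rng.normal(0.0, noise_sigma, size=t.shape)
    truth = {"lam": lam, "kap": kap, "theta": theta,
             "noise_sigma": noise_sigma, "flocculation_rate": flocculation_rate,
             "seed": seed}
    return ThTTrace(t, y, well_id, condition or {}), truth


# ------------------------------------------------------------ κ(I) series


def gen_kappa_vs_I(model: str, params: dict, I_grid=DEFAULT_I_GRID_MM,
                   noise_frac: float = 0.0, n_replicates: int = 1,
                   seed: int = 0) -> tuple[np.ndarray, dict]:
    """κ(I) points from one of the two ionic-strength models.

    The default I grid mirrors 20 mM sodium phosphate pH 7.4 plus
    0–400 mM NaCl; ``n_replicates`` independent κ draws per ionic
    strength emulate the per-replicate kinetic fits that feed the salt
    models.  ``noise_frac`` applies multiplicative Gaussian noise.
    Returns an (n, 2) array of (I mM, κ h⁻¹).
    """
    rng = np.random.default_rng(seed)
    I = np.repeat(np.asarray(I_grid, float), n_replicates)
    if model in ("free_energy_barrier", "feb"):
        kap = feb_model(I, params["kappa0"], params["kappa_sat"],
                        params["I_mid"])
    elif model in ("bronsted_bjerrum", "bb"):
        kap = bb_model(I, params["kappa0"], params["I_2"])
    else:
        raise ValueError(f"unknown model {model!r}")
    kap = kap * (1.0 + noise_frac * rng.standard_normal(I.shape))
    truth = {"model": model, "params": dict(params),
             "noise_frac": noise_frac, "n_replicates": n_replicates,
             "seed": seed}
    return np.column_stack([I, kap]), truth


# ------------------------------------------------------------ seeded pairs


def gen_seeded_pair(k: float, kappa: float, r: float = 0.1, dt: float = 15.0,
                    fragmentation: bool = True, noise_sigma: float = 0.02,
                    t_grid=None, n_replicates: int = 3, seed: int = 0
                    ) -> tuple[list[ThTTrace], list[ThTTrace], dict]:
    """Two seeded-growth trace sets Δt of fibril aging apart.

    The first set grows at rate k.  Under the fragmentation model the
    aged-seed set grows at k′ = k + κ²·r·Δt; without fragmentation the
    seeds do not gain ends and k′ = k.
    """
    rng = np.random.default_rng(seed)
    k_prime = k + (kappa**2 * r * dt if fragmentation else 0.0)
    if t_grid is None:
        t_grid = np.linspace(0.0, 5.0 / max(k, 1e-6), 60)
    t = np.asarray(t_grid, float)

    def make(rate, tag):
        out = []
        for i in range(n_replicates):
            y = seeded_curve(t, 1.0, rate) + rng.normal(0, noise_sigma, t.shape)
            out.append(ThTTrace(t, y, f"{tag}-{i}"))
        return out

    first = make(k, "fresh")
    second = make(k_prime, "aged")
    truth = {"k": k, "k_prime": k_prime, "kappa": kappa, "r": r, "dt": dt,
             "fragmentation": fragmentation, "noise_sigma": noise_sigma,
             "seed": seed}
    return first, second, truth


# ------------------------------------------------------------ toy ensembles


def _gaussian_chain(rng, n_res, n_frames, bond=0.38):
    steps = rng.normal(0.0, bond / np.sqrt(3.0), size=(n_frames, n_res - 1, 3))
    frames = np.concatenate([np.zeros((n_frames, 1, 3)),
                             np.cumsum(steps, axis=1)], axis=1)
    return frames


def _tethered_chain(rng, n_res, n_frames, bond=0.38, tether_frac=0.15,
                    contraction=0.6):
    """Tethered-compact conformers: a Gaussian chain conditioned (Brownian
    bridge) on a short end-to-end vector, then uniformly contracted —
    globally compact with a long-range N–C contact."""
    frames = _gaussian_chain(rng, n_res, n_frames, bond)
    target_len = tether_frac * bond * np.sqrt(n_res - 1)
    targets = rng.normal(0.0, target_len / np.sqrt(3.0), size=(n_frames, 3))
    ree = frames[:, -1, :] - frames[:, 0, :]
    frac = np.arange(n_res)[None, :, None] / (n_res - 1)
    return contraction * (frames - frac * (ree - targets)[:, None, :])


def gen_toy_ensemble(n_res: int, n_frames: int, mode: str = "ideal",
                     mixture_weight: float = 0.6, seed: int = 0,
                     bond: float = 0.38, max_tries: int = 200
                     ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Toy conformational ensembles with known ground truth.

    Modes: ``ideal`` (Gaussian chain, ν = 1/2), ``self_avoiding_proxy``
    (step-wise regrowth with overlap rejection, swollen ν > 1/2) and
    ``nc_tethered_mixture`` (a ``mixture_weight`` fraction of compact
    end-to-end-tethered chains, label 1, mixed with free chains, label
    0).  Returns (frames, labels, truth).
    """
    if n_res < 20:
        raise ValueError("need at least 20 residues")
    rng = np.random.default_rng(seed)
    if mode == "ideal":
        frames = _gaussian_chain(rng, n_res, n_frames, bond)
        labels = np.zeros(n_frames, dtype=int)
    elif mode == "self_avoiding_proxy":
        cutoff = 0.75 * bond
        frames = np.empty((n_frames, n_res, 3))
        for f in range(n_frames):
            chain = np.zeros((n_res, 3))
            for i in range(1, n_res):
                for attempt in range(max_tries):
                    step = rng.normal(0.0, bond / np.sqrt(3.0), 3)
                    cand = chain[i - 1] + step
                    d2 = ((chain[:max(i - 1, 1)] - cand) ** 2).sum(axis=1)
                    if np.all(d2 > cutoff**2):
                        chain[i] = cand
                        break
                else:
                    raise RuntimeError(
                        f"rejection sampling stalled at frame {f}, bead {i} "
                        f"after {max_tries} tries; lower the overlap cutoff")
            frames[f] = chain
        labels = np.zeros(n_frames, dtype=int)
    elif mode == "nc_tethered_mixture":
        # two families of closely interrelated conformers: frames jitter
        # around a compact (end-to-end-tethered, contracted) reference and
        # an expanded free-chain reference, emulating compact-vs-expanded
        # classes within a continuous conformational spectrum
        n_teth = int(round(mixture_weight * n_frames))
        ref_c = _tethered_chain(rng, n_res, 1, bond)[0]
        rg = lambda x: float(np.sqrt(((x - x.mean(0)) ** 2).sum(1).mean()))
        for _ in range(max_tries):
            ref_e = _gaussian_chain(rng, n_res, 1, bond)[0]
            if rg(ref_e) > 1.5 * rg(ref_c):
                break
        else:
            raise RuntimeError("could not draw an expanded reference larger "
                               "than the compact one")
        sigma = 0.4 * bond
        teth = ref_c[None] + rng.normal(0, sigma, (n_teth, n_res, 3))
        free = ref_e[None] + rng.normal(0, sigma,
                                        (n_frames - n_teth, n_res, 3))
        frames = np.concatenate([teth, free], axis=0)
        labels = np.concatenate([np.ones(n_teth, int),
                                 np.zeros(n_frames - n_teth, int)])
        perm = rng.permutation(n_frames)
        frames, labels = frames[perm], labels[perm]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    truth = {"mode": mode, "n_res": n_res, "n_frames": n_frames,
             "mixture_weight": mixture_weight, "bond": bond, "seed": seed}
    return frames, labels, truth


# ------------------------------------------------------------ Taylorgrams


def gen_taylorgram(rh_nm: float, t_r_s: float = 180.0, snr: float = 100.0,
                   n_points: int = 2000, baseline_slope: float = 0.0,
                   baseline_offset: float = 0.0, seed: int = 0,
                   **instrument) -> tuple[Taylorgram, dict]:
    """Gaussian Taylorgram for a species of known hydrodynamic radius."""
    rng = np.random.default_rng(seed)
    tg0 = Taylorgram(np.zeros(2), np.zeros(2), **instrument)
    sigma_t2 = expected_sigma_t2(rh_nm, t_r_s, tg0.capillary_radius_um,
                                 tg0.temperature_K, tg0.viscosity_mPas)
    sigma = np.sqrt(sigma_t2)
    t = np.linspace(t_r_s - 8 * sigma, t_r_s + 8 * sigma, n_points)
    y = np.exp(-0.5 * ((t - t_r_s) / sigma) ** 2)
    y = y + baseline_offset + baseline_slope * (t - t[0])
    y = y + rng.normal(0.0, 1.0 / snr, size=t.shape)
    truth = {"rh_nm": rh_nm, "t_r_s": t_r_s, "sigma_t2": sigma_t2,
             "snr": snr, "seed": seed}
    return Taylorgram(t, y, tg0.capillary_radius_um, tg0.capillary_length_m,
                      tg0.temperature_K, tg0.viscosity_mPas), truth


# ------------------------------------------------------------ observation table


def gen_observation_table(planted_pairs: list[tuple[int, int]],
                          effect_sizes: list[float],
                          mask: set[tuple[int, int]],
                          variants: tuple[str, ...] = ("FL", "d3", "d5", "d3d5"),
                          I_grid=DEFAULT_I_GRID_MM,
                          distance_noise_nm: float = 0.05,
                          metric_noise: float = 0.02, seed: int = 0
                          ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Observation table plus per-pair distances with planted κ links.

    κ increases with ionic strength (saturating) and differs between
    variants; the shape metrics are monotone functions of κ plus noise.
    Planted pairs get a mean distance that varies linearly with log κ at
    the given effect size (nm per e-fold of κ; negative plants a
    negative correlation); all other pairs get distances independent of
    κ.  Only pairs in ``mask`` are emitted.
    """
    if len(planted_pairs) != len(effect_sizes):
        raise ValueError("planted_pairs and effect_sizes differ in length")
    for p in planted_pairs:
        if tuple(p) not in mask:
            raise ValueError(f"planted pair {p} not in the unmasked set")
    rng = np.random.default_rng(seed)
    rows, drows = [], []
    base_kap = {v: 0.3 * (1.6 ** i) for i, v in enumerate(variants)}
    pair_base = {p: 1.5 + 0.5 * rng.random() for p in map(tuple, mask)}
    for v in variants:
        for I in I_grid:
            kap = feb_model(I, base_kap[v], 4.0 * base_kap[v], 150.0)
            kap *= np.exp(0.05 * rng.standard_normal())
            logk = np.log(kap)
            rows.append({
                "variant": v, "I_mM": float(I),
                "lam": 0.05 * np.exp(0.3 * rng.standard_normal()),
                "kap": float(kap),
                "pct_insoluble": float(np.clip(70 + 10 * logk
                                               + 5 * rng.standard_normal(), 0, 100)),
                "delta": float(0.45 + 0.05 * logk
                               + metric_noise * rng.standard_normal()),
                "S": float(0.6 + 0.3 * logk
                           + metric_noise * rng.standard_normal()),
                "nu": float(0.52 + 0.02 * logk
                            + 0.2 * metric_noise * rng.standard_normal()),
            })
            planted = dict(zip(map(tuple, planted_pairs), effect_sizes))
            for (i, j), d0 in pair_base.items():
                eff = planted.get((i, j), 0.0)
                d = d0 + eff * logk + distance_noise_nm * rng.standard_normal()
                drows.append({"variant": v, "I_mM": float(I), "i": i, "j": j,
                              "mean_d_nm": float(d)})
    truth = {"planted_pairs": [tuple(p) for p in planted_pairs],
             "effect_sizes": list(effect_sizes), "seed": seed}
    return pd.DataFrame(rows), pd.DataFrame(drows), truth
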