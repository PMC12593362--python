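"""Conformational observables and conformer classification for CG ensembles.

Per-frame observables come from the gyration tensor (Rg, asphericity Δ,
prolateness S) and from internal distance scaling (the Flory exponent ν,
fitted from √⟨R_ij²⟩ = R0·|i−j|^ν over sequence separations ≥ 10).
Contact maps report, for every nonbonded residue pair, the fraction of
frames within a 2.0 nm (20 Å) Cα–Cα distance threshold.

Frames are classified by spectral clustering of a frame–frame affinity
matrix, a Gaussian kernel of the mean squared deviation in inter-residue
distances

    A_xy = exp[ − ⟨(d_ij,x − d_ij,y)²⟩ / ⟨2·Var(d_ij)⟩ ],

where ⟨···⟩ averages over all nonbonded pairs (i > j+1), separately in
the numerator and denominator, and Var(d_ij) is the variance of d_ij
over frames; 2·Var(d_ij) is the expected squared deviation for two
i.i.d. frames.  Classes are relabelled 1..k by ascending mean Rg so
that class 1 is always the most compact.

The resulting classes are subdivisions of a spectrum of conformations,
not well-separated free-energy basins; reports carry this caveat in
their metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import SpectralClustering

#: Interpretation caveat attached to every cluster report.
CLUSTER_CAVEAT = ("clusters are subdivisions of a spectrum of conformations, "
                  "not well-separated free-energy basins")

DEFAULT_CONTACT_THRESHOLD = 2.0  # nm


@dataclass
class EnsembleMetrics:
    rg_mean: float
    rg_err: float
    asphericity: float
    asphericity_err: float
    prolateness: float
    prolateness_err: float
    rg_frames: np.ndarray = field(repr=False)
    asphericity_frames: np.ndarray = field(repr=False)
    prolateness_frames: np.ndarray = field(repr=False)


@dataclass
class ContactMap:
    matrix: np.ndarray          # (N, N), NaN on masked entries
    threshold: float

    def to_long(self) -> pd.DataFrame:
        n = self.matrix.shape[0]
        i, j = np.triu_indices(n, k=2)
        return pd.DataFrame({"i": i + 1, "j": j + 1, "p": self.matrix[i, j]})


@dataclass
class ClusterResult:
    labels: np.ndarray                  # per-frame class in 1..k
    populations: np.ndarray             # percent of frames per class (1..k)
    affinity: np.ndarray = field(repr=False)
    representative_frames: np.ndarray = field(default=None)
    caveat: str = CLUSTER_CAVEAT

    @property
    def k(self) -> int:
        return len(self.populations)


def _as_frames(frames: np.ndarray) -> np.ndarray:
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must have shape (F, N, 3)")
    return frames


def _bootstrap_err(x: np.ndarray, n_boot: int = 200, seed: int = 0) -> float:
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(n_boot, len(x)))
    return float(np.std(x[idx].mean(axis=1), ddof=1))


def gyration_metrics(frames: np.ndarray, n_boot: int = 200,
                     seed: int = 0) -> EnsembleMetrics:
    """Rg, asphericity Δ and prolateness S from the gyration tensor.

    With eigenvalues λ1 ≥ λ2 ≥ λ3 of the per-frame (mass-uniform)
    gyration tensor and λ̄ their mean, the ensemble descriptors are the
    deviatoric invariant ratios with numerator and denominator averaged
    over frames separately:

        Rg = √⟨λ1+λ2+λ3⟩,   Δ = (3/2)·⟨Σ(λi−λ̄)²⟩ / ⟨(Σλi)²⟩,
        S  = 27·⟨Π(λi−λ̄)⟩ / ⟨(Σλi)³⟩.

    Δ ∈ [0, 1] (0 = sphere, 1 = rod; ideal chains give 10/19 ≈ 0.53);
    S ∈ [−1/4, 2] (rod = 2, oblate < 0).  Errors are bootstrap standard
    errors over frames of the same ratio-of-means; ``*_frames`` fields
    hold per-frame ratios for diagnostics.
    """
    frames = _as_frames(frames)
    centred = frames - frames.mean(axis=1, keepdims=True)
    if np.any(np.all(np.ptp(frames, axis=1) == 0, axis=1)):
        raise ValueError("degenerate frame: all beads coincide")
    # gyration tensors, (F, 3, 3)
    tensors = np.einsum("fni,fnj->fij", centred, centred) / frames.shape[1]
    evals = np.linalg.eigvalsh(tensors)          # ascending
    tr = evals.sum(axis=1)
    dev = evals - tr[:, None] / 3.0
    rg = np.sqrt(tr)
    dev2 = (dev**2).sum(axis=1)
    dev3 = dev.prod(axis=1)
    delta = 1.5 * dev2.mean() / (tr**2).mean()
    s = 27.0 * dev3.mean() / (tr**3).mean()

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(tr), size=(n_boot, len(tr)))
    delta_b = 1.5 * dev2[idx].mean(axis=1) / (tr[idx]**2).mean(axis=1)
    s_b = 27.0 * dev3[idx].mean(axis=1) / (tr[idx]**3).mean(axis=1)
    return EnsembleMetrics(
        float(rg.mean()), _bootstrap_err(rg, n_boot, seed),
        float(delta), float(np.std(delta_b, ddof=1)),
        float(s), float(np.std(s_b, ddof=1)),
        rg, 1.5 * dev2 / tr**2, 27.0 * dev3 / tr**3)


def internal_distance_scaling(frames: np.ndarray) -> pd.DataFrame:
    """√⟨R_ij²⟩ (over frames and pairs) as a function of |i−j|."""
    frames = _as_frames(frames)
    n = frames.shape[1]
    seps = np.arange(1, n)
    rms = np.empty(n - 1)
    for s in seps:
        d2 = ((frames[:, s:, :] - frames[:, :-s, :]) ** 2).sum(axis=2)
        rms[s - 1] = np.sqrt(d2.mean())
    return pd.DataFrame({"separation": seps, "rms_distance": rms})


def flory_exponent(frames: np.ndarray, min_separation: int = 10
                   ) -> tuple[float, float, float]:
    """Flory exponent ν from internal distance scaling.

    Least-squares fit of log √⟨R_ij²⟩ against log |i−j| for separations
    ≥ ``min_separation``.  Returns (nu, standard error, R0 in nm).
    """
    frames = _as_frames(frames)
    if frames.shape[1] < 20:
        raise ValueError("chain too short for a Flory fit (need ≥ 20 residues)")
    prof = internal_distance_scaling(frames)
    sel = prof[prof.separation >= min_separation]
    x = np.log(sel.separation.to_numpy(float))
    y = np.log(sel.rms_distance.to_numpy(float))
    (nu, logr0), cov = np.polyfit(x, y, 1, cov=True)
    return float(nu), float(np.sqrt(cov[0, 0])), float(np.exp(logr0))


def _pair_indices(n: int, min_sep: int = 2) -> tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(n, k=min_sep)
    return i, j


def pairwise_distances(frames: np.ndarray, min_sep: int = 2) -> np.ndarray:
    """Condensed Cα–Cα distances, shape (F, P) over pairs with j ≥ i+min_sep."""
    frames = _as_frames(frames)
    i, j = _pair_indices(frames.shape[1], min_sep)
    return np.sqrt(((frames[:, i, :] - frames[:, j, :]) ** 2).sum(axis=2))


def contact_map(frames: np.ndarray,
                threshold: float = DEFAULT_CONTACT_THRESHOLD) -> ContactMap:
    """Fraction of frames with d_ij ≤ threshold; |i−j| ≤ 1 masked (NaN)."""
    frames = _as_frames(frames)
    n = frames.shape[1]
    d = pairwise_distances(frames, min_sep=2)
    p = (d <= threshold).mean(axis=0)
    mat = np.full((n, n), np.nan)
    i, j = _pair_indices(n, 2)
    mat[i, j] = p
    mat[j, i] = p
    return ContactMap(mat, threshold)


def affinity_matrix(frames: np.ndarray,
                    distances: np.ndarray | None = None) -> np.ndarray:
    """Frame–frame Gaussian-kernel affinity over inter-residue distances.

    ``distances`` may pass precomputed condensed distances (from
    :func:`pairwise_distances` with ``min_sep=2``) to avoid recomputation.
    """
    if distances is None:
        distances = pairwise_distances(frames, min_sep=2)
    d = np.asarray(distances, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] < 2:
        raise ValueError("need at least two frames")
    f, p = d.shape
    denom = 2.0 * d.var(axis=0, ddof=0).mean()
    if denom <= 1e-12 * max(float((d * d).mean()), 1e-300):
        raise ValueError("static ensemble: every pair distance is constant, "
                         "affinity kernel undefined")
    sq = (d * d).sum(axis=1)
    gram = d @ d.T
    msd = (sq[:, None] + sq[None, :] - 2.0 * gram) / p
    np.maximum(msd, 0.0, out=msd)
    a = np.exp(-msd / denom)
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 1.0)
    return a


def cluster_conformers(affinity: np.ndarray, frames: np.ndarray,
                       k: int = 4, seed: int = 0) -> ClusterResult:
    """Spectral clustering of frames; classes ordered by ascending mean Rg.

    Class 1 is the most compact.  The RNG seed fixes the k-means step of
    the spectral embedding so repeated runs agree.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    frames = _as_frames(frames)
    model = SpectralClustering(n_clusters=k, affinity="precomputed",
                               random_state=seed, assign_labels="kmeans")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign graph-connectivity notices
        raw = model.fit_predict(affinity)
    centred = frames - frames.mean(axis=1, keepdims=True)
    rg = np.sqrt((centred**2).sum(axis=2).mean(axis=1))
    order = np.argsort([rg[raw == c].mean() for c in range(k)])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw]
    pops = np.array([(labels == c).mean() * 100.0 for c in range(1, k + 1)])
    reps = np.array([representative_frame(affinity, labels, c)
                     for c in range(1, k + 1)])
    return ClusterResult(labels, pops, affinity, reps)


def representative_frame(affinity: np.ndarray, labels: np.ndarray,
                         class_id: int) -> int:
    """Frame maximising mean affinity to the other members of its class.

    Ties break toward the lowest frame index; a singleton class returns
    its only member.
    """
    members = np.flatnonzero(labels == class_id)
    if members.size == 0:
        raise ValueError(f"class {class_id} is empty")
    if members.size == 1:
        return int(members[0])
    sub = affinity[np.ix_(members, members)]
    mean_aff = (sub.sum(axis=1) - np.diag(sub)) / (members.size - 1)
    return int(members[np.argmax(mean_aff)])


def cluster_report(result: ClusterResult) -> dict:
    """JSON-ready cluster summary (populations, representatives, caveat)."""
    return {
        "k": result.k,
        "populations_pct": [round(float(p), 3) for p in result.populations],
        "representative_frames": [int(r) for r in result.representative_frames],
        "caveat": result.caveat,
    }


def write_ca_pdb(frame: np.ndarray, path, sequence: str | None = None) -> None:
    """Write one conformer as a Cα-only PDB (for molecular viewers).

    Coordinates are in nm and converted to Å; ``sequence`` supplies
    one-letter residue names (defaults to alanine).
    """
    three = {"A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
             "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
             "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
             "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL"}
    frame = np.asarray(frame, float)
    seq = sequence or "A" * len(frame)
    with open(path, "w") as fh:
        for i, ((x, y, z), aa) in enumerate(zip(frame * 10.0, seq), start=1):
            fh.write(f"ATOM  {i:>5}  CA  {three.get(aa, 'UNK')} A{i:>4}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
        fh.write("END\n")


def metrics_table(frames: np.ndarray, **kwargs) -> pd.DataFrame:
    """Per-frame Rg/Δ/S table (TSV-friendly)."""
    m = gyration_metrics(frames, **kwargs)
    return pd.DataFrame({"frame": np.arange(len(m.rg_frames)),
                         "rg_nm": m.rg_frames,
                         "asphericity": m.asphericity_frames,
                         "prolateness": m.prolateness_frames})
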