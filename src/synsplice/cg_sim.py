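"""Single-chain coarse-grained Langevin simulator in the CALVADOS style.

One bead per residue; harmonic bonds (b = 0.38 nm, k = 8033 kJ/mol/nm²);
nonbonded interactions between beads separated by at least two bonds via

* a truncated-and-shifted Ashbaugh–Hatch potential (a Lennard-Jones form
  whose attractive tail is scaled by the mean per-residue "stickiness"
  λ̄ = (λi + λj)/2; cutoff 2.0 nm), and
* a truncated Debye–Hückel potential for screened electrostatics
  (cutoff 4.0 nm), with the Debye length set by the solution ionic
  strength and a temperature-dependent water dielectric.

Dynamics are integrated with a BAOAB Langevin splitting (dt = 10 fs,
friction 0.01 ps⁻¹ by default) in a cubic periodic box of edge
0.76·(N−1) + 4 nm; since the box edge exceeds twice the contour length,
the minimum-image convention is exact for a single chain.  Units follow
the GROMACS convention: nm, ps, kJ/mol, Da (then kB = 0.00831446
kJ/mol/K and velocities come out in nm/ps).

The published CALVADOS 2 residue table (σ, λ, q, mass) is embedded but
fully swappable, so the same machinery runs with toy parameter sets
(ideal chains, purely repulsive chains) in tests.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .sequences import SpliceVariant

# ------------------------------------------------------------------ constants

KB = 0.00831446261815324          # kJ/mol/K
_COULOMB = 138.935458             # e^2/(4 pi eps0) in kJ mol^-1 nm e^-2

EPS_AH = 0.8368                   # Ashbaugh–Hatch energy scale, kJ/mol (0.2 kcal/mol)
CUTOFF_AH = 2.0                   # nm, truncated-shifted
CUTOFF_DH = 4.0                   # nm, truncated
HIS_PKA = 6.0

# Published CALVADOS 2 residue parameters: sigma (nm), stickiness lambda,
# formal charge (e; His handled separately as pH-dependent), mass (Da).
CALVADOS2_TABLE: dict[str, tuple[float, float, float, float]] = {
    #      sigma   lambda                 q      mass
    "A": (0.504, 0.2743297969040348, 0.0, 71.07),
    "R": (0.656, 0.7307624767517166, 1.0, 156.19),
    "N": (0.568, 0.4255859009787713, 0.0, 114.10),
    "D": (0.558, 0.0416040480605567, -1.0, 115.09),
    "C": (0.548, 0.5615435099141777, 0.0, 103.14),
    "Q": (0.602, 0.3934318551056041, 0.0, 128.13),
    "E": (0.592, 0.0006935460962935, -1.0, 129.11),
    "G": (0.450, 0.7058843733666401, 0.0, 57.05),
    "H": (0.608, 0.4663667290557992, 0.0, 137.14),
    "I": (0.618, 0.5423623610671892, 0.0, 113.16),
    "L": (0.618, 0.6440005007782226, 0.0, 113.16),
    "K": (0.636, 0.1790211738990582, 1.0, 128.17),
    "M": (0.618, 0.5308481134337497, 0.0, 131.20),
    "F": (0.636, 0.8672358982062975, 0.0, 147.18),
    "P": (0.556, 0.3593126576364644, 0.0, 97.12),
    "S": (0.518, 0.4625416811611541, 0.0, 87.08),
    "T": (0.562, 0.3713162976273964, 0.0, 101.11),
    "W": (0.678, 0.9893764740371644, 0.0, 186.21),
    "Y": (0.646, 0.9774611449343455, 0.0, 163.18),
    "V": (0.586, 0.2083769608174481, 0.0, 99.07),
}


def default_parameters() -> pd.DataFrame:
    """CALVADOS 2 residue parameter table (index: one-letter code)."""
    df = pd.DataFrame.from_dict(
        CALVADOS2_TABLE, orient="index",
        columns=["sigma", "lambda_", "charge", "mass"])
    df.index.name = "residue"
    return df


def water_dielectric(T: float) -> float:
    """Empirical relative permittivity of water as a function of T (K)."""
    return 5321.0 / T + 233.76 - 0.9297 * T + 1.417e-3 * T**2 - 8.292e-7 * T**3


def debye_length(ionic_strength_mM: float, T: float = 298.0) -> float:
    """Debye screening length (nm) of a 1:1 electrolyte.

    λ_D = sqrt(ε0 εr(T) kB T / (2 NA e² I)); evaluated in simulation
    units this is sqrt(εr kB T / (8 π lB_vac I)) with the vacuum Bjerrum
    factor folded into ``_COULOMB``.
    """
    if ionic_strength_mM <= 0:
        raise ValueError("ionic strength must be positive (no-screening limit "
                         "is not representable by a finite Debye length)")
    eps_r = water_dielectric(T)
    I = ionic_strength_mM * 1e-3 * 6.02214076e23 * 1e-24  # ions / nm^3
    return math.sqrt(eps_r * KB * T / (8.0 * math.pi * _COULOMB * I))


def his_charge(pH: float, pka: float = HIS_PKA) -> float:
    """Fractional His charge from Henderson–Hasselbalch."""
    return 1.0 / (1.0 + 10.0 ** (pH - pka))


@dataclass
class SimProtocol:
    """Simulation protocol; defaults are the standard αSyn monomer setup."""

    bond_length: float = 0.38          # nm
    bond_k: float = 8033.0             # kJ/mol/nm^2
    dt_ps: float = 0.01                # 10 fs
    friction_ps: float = 0.01          # ps^-1
    temperature_K: float = 310.0
    pH: float = 7.4
    ionic_strength_mM: float = 150.0
    production_ns: float = 350.0
    equilibration_ps: float = 700.0
    frame_interval_ps: float = 70.0
    eps_ah: float = EPS_AH             # set 0 to switch all nonbonded terms off
    charges_on: bool = True
    terminal_charges: bool = True      # +1 N-terminus, −1 C-terminus

    def box_edge(self, n_residues: int) -> float:
        return 0.76 * (n_residues - 1) + 4.0


@dataclass
class Trajectory:
    frames: np.ndarray                 # (F, N, 3) nm
    frame_times_ps: np.ndarray
    sequence: str
    variant_name: str
    seed: int
    protocol: SimProtocol
    frame_velocities: np.ndarray | None = field(default=None, repr=False)
    masses: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def to_xyz(self, path: str | Path) -> None:
        """Plain-text XYZ (coordinates in nm) plus a JSON sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            for f, t in zip(self.frames, self.frame_times_ps):
                fh.write(f"{len(self.sequence)}\n")
                fh.write(f"t_ps={t:.3f}\n")
                for aa, (x, y, z) in zip(self.sequence, f):
                    fh.write(f"{aa} {x:.5f} {y:.5f} {z:.5f}\n")
        sidecar = {
            "variant": self.variant_name, "sequence": self.sequence,
            "seed": self.seed, "protocol": asdict(self.protocol),
        }
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_xyz(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        frames, times = [], []
        with open(path) as fh:
            lines = fh.read().split("\n")
        i = 0
        seq = ""
        while i < len(lines) and lines[i].strip():
            n = int(lines[i])
            times.append(float(lines[i + 1].split("=")[1]))
            block = lines[i + 2:i + 2 + n]
            seq = "".join(l.split()[0] for l in block)
            frames.append([[float(v) for v in l.split()[1:4]] for l in block])
            i += 2 + n
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            with open(sidecar_path) as fh:
                meta = json.load(fh)
            proto = SimProtocol(**meta["protocol"])
            name, seed = meta["variant"], meta["seed"]
        else:
            proto, name, seed = SimProtocol(), "unknown", -1
        return cls(np.asarray(frames), np.asarray(times), seq, name, seed, proto)


# ------------------------------------------------------------------ kernels


@njit(cache=True, fastmath=True)
def _build_neighbour_lists(pos, box, rl_ah2, rl_dh2, qq,
                           ah_i, ah_j, dh_i, dh_j):
    n = pos.shape[0]
    na = nd = 0
    for i in range(n):
        xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
        for j in range(i + 2, n):
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rl_ah2:
                ah_i[na] = i
                ah_j[na] = j
                na += 1
            if qq[i, j] != 0.0 and r2 < rl_dh2:
                dh_i[nd] = i
                dh_j[nd] = j
                nd += 1
    return na, nd


@njit(cache=True, fastmath=True)
def _forces(pos, box, forces, sig2, lam, qq, eps, rc_ah2, rc_dh2,
            inv_ld, bond_b, bond_k, ah_i, ah_j, na, dh_i, dh_j, nd):
    n = pos.shape[0]
    forces[:] = 0.0
    # bonds
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        f = bond_k * (r - bond_b) / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[i + 1, 0] -= f * dx
        forces[i + 1, 1] -= f * dy
        forces[i + 1, 2] -= f * dz
    # Ashbaugh–Hatch
    if eps > 0.0:
        for p in range(na):
            i = ah_i[p]
            j = ah_j[p]
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= rc_ah2:
                continue
            s2 = sig2[i, j]
            sr2 = s2 / r2
            sr6 = sr2 * sr2 * sr2
            sr12 = sr6 * sr6
            # dU/dr / r for the LJ core
            g = 24.0 * eps * (2.0 * sr12 - sr6) / r2
            if r2 > 1.259921049894873 * s2:      # r > 2^(1/6) sigma
                g *= lam[i, j]
            forces[i, 0] -= g * dx
            forces[i, 1] -= g * dy
            forces[i, 2] -= g * dz
            forces[j, 0] += g * dx
            forces[j, 1] += g * dy
            forces[j, 2] += g * dz
    # Debye–Hückel
    for p in range(nd):
        i = dh_i[p]
        j = dh_j[p]
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        dx -= box * round(dx / box)
        dy -= box * round(dy / box)
        dz -= box * round(dz / box)
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= rc_dh2:
            continue
        r = math.sqrt(r2)
        u = qq[i, j] * math.exp(-r * inv_ld) / r
        g = u * (1.0 / r + inv_ld) / r
        forces[i, 0] -= g * dx
        forces[i, 1] -= g * dy
        forces[i, 2] -= g * dz
        forces[j, 0] += g * dx
        forces[j, 1] += g * dy
        forces[j, 2] += g * dz


@njit(cache=True, fastmath=True)
def _potential_energy(pos, box, sig2, lam, qq, eps, rc_ah2, rc_dh2,
                      inv_ld, bond_b, bond_k):
    """Total potential energy (kJ/mol); AH truncated-shifted, DH truncated."""
    n = pos.shape[0]
    e = 0.0
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = math.sqrt(dx * dx + dy * dy + dz * dz)
        e += 0.5 * bond_k * (r - bond_b) ** 2
    for i in range(n):
        for j in range(i + 2, n):
            dx = pos[j, 0] - pos[i, 0]
            dy = pos[j, 1] - pos[i, 1]
            dz = pos[j, 2] - pos[i, 2]
            dx -= box * round(dx / box)
            dy -= box * round(dy / box)
            dz -= box * round(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if eps > 0.0 and r2 < rc_ah2:
                s2 = sig2[i, j]
                l = lam[i, j]
                sr2 = s2 / r2
                sr6 = sr2 * sr2 * sr2
                ulj = 4.0 * eps * (sr6 * sr6 - sr6)
                src2 = s2 / rc_ah2
                src6 = src2 * src2 * src2
                shift = l * 4.0 * eps * (src6 * src6 - src6)
                if r2 <= 1.259921049894873 * s2:
                    e += ulj + (1.0 - l) * eps - shift
                else:
                    e += l * ulj - shift
            if qq[i, j] != 0.0 and r2 < rc_dh2:
                r = math.sqrt(r2)
                e += qq[i, j] * math.exp(-r * inv_ld) / r
    return e


@njit(cache=True, fastmath=True)
def _run(pos, vel, masses, box, sig2, lam, qq, eps, inv_ld,
         bond_b, bond_k, dt, friction, kbt,
         n_steps, save_every, n_frames, skin, seed):
    """BAOAB Langevin integration; returns (frames, frame_vels, ok_flag)."""
    np.random.seed(seed)
    n = pos.shape[0]
    frames = np.empty((n_frames, n, 3))
    frame_vels = np.empty((n_frames, n, 3))
    forces = np.empty((n, 3))
    rc_ah2 = CUTOFF_AH * CUTOFF_AH
    rc_dh2 = CUTOFF_DH * CUTOFF_DH
    rl_ah2 = (CUTOFF_AH + skin) ** 2
    rl_dh2 = (CUTOFF_DH + skin) ** 2
    max_pairs = n * (n - 1) // 2
    ah_i = np.empty(max_pairs, dtype=np.int32)
    ah_j = np.empty(max_pairs, dtype=np.int32)
    dh_i = np.empty(max_pairs, dtype=np.int32)
    dh_j = np.empty(max_pairs, dtype=np.int32)
    na, nd = _build_neighbour_lists(pos, box, rl_ah2, rl_dh2, qq,
                                    ah_i, ah_j, dh_i, dh_j)
    ref = pos.copy()
    half_skin2 = (0.5 * skin) ** 2

    if friction > 0.0:
        c1 = math.exp(-friction * dt)
        c2 = math.sqrt(kbt * (1.0 - c1 * c1))
    else:
        c1 = 1.0
        c2 = 0.0
    half_dt = 0.5 * dt

    _forces(pos, box, forces, sig2, lam, qq, eps, rc_ah2, rc_dh2,
            inv_ld, bond_b, bond_k, ah_i, ah_j, na, dh_i, dh_j, nd)

    saved = 0
    for step in range(n_steps):
        for i in range(n):
            inv_m = 1.0 / masses[i]
            for d in range(3):
                vel[i, d] += half_dt * forces[i, d] * inv_m
                pos[i, d] += half_dt * vel[i, d]
        if c2 > 0.0:
            noise = np.random.standard_normal((n, 3))
            for i in range(n):
                sm = c2 / math.sqrt(masses[i])
                for d in range(3):
                    vel[i, d] = c1 * vel[i, d] + sm * noise[i, d]
        for i in range(n):
            for d in range(3):
                pos[i, d] += half_dt * vel[i, d]
        # neighbour-list refresh when anything moved half a skin
        max_d2 = 0.0
        for i in range(n):
            d2 = ((pos[i, 0] - ref[i, 0]) ** 2 + (pos[i, 1] - ref[i, 1]) ** 2
                  + (pos[i, 2] - ref[i, 2]) ** 2)
            if d2 > max_d2:
                max_d2 = d2
        if max_d2 > half_skin2:
            na, nd = _build_neighbour_lists(pos, box, rl_ah2, rl_dh2, qq,
                                            ah_i, ah_j, dh_i, dh_j)
            ref[:] = pos
        _forces(pos, box, forces, sig2, lam, qq, eps, rc_ah2, rc_dh2,
                inv_ld, bond_b, bond_k, ah_i, ah_j, na, dh_i, dh_j, nd)
        for i in range(n):
            inv_m = 1.0 / masses[i]
            for d in range(3):
                vel[i, d] += half_dt * forces[i, d] * inv_m
        if (step + 1) % save_every == 0 and saved < n_frames:
            ok = True
            for i in range(n):
                for d in range(3):
                    frames[saved, i, d] = pos[i, d]
                    frame_vels[saved, i, d] = vel[i, d]
                    if not math.isfinite(pos[i, d]):
                        ok = False
            if not ok:
                return frames[:saved], frame_vels[:saved], False
            saved += 1
    return frames[:saved], frame_vels[:saved], True


# ------------------------------------------------------------------ setup


def chain_parameters(sequence: str, protocol: SimProtocol,
                     params: pd.DataFrame | None = None):
    """Per-bead σ/λ/q/mass arrays with terminal adjustments applied."""
    if params is None:
        params = default_parameters()
    missing = set(sequence) - set(params.index)
    if missing:
        raise ValueError(f"parameter table lacks residues {sorted(missing)}")
    sig = params.loc[list(sequence), "sigma"].to_numpy(float)
    lam = params.loc[list(sequence), "lambda_"].to_numpy(float)
    q = params.loc[list(sequence), "charge"].to_numpy(float).copy()
    mass = params.loc[list(sequence), "mass"].to_numpy(float).copy()
    qh = his_charge(protocol.pH)
    q[np.array(list(sequence)) == "H"] = qh
    if protocol.terminal_charges:
        q[0] += 1.0
        q[-1] -= 1.0
    mass[0] += 2.0    # extra H2 at the N-terminus
    mass[-1] += 16.0  # extra O at the C-terminus
    if not protocol.charges_on:
        q[:] = 0.0
    return sig, lam, q, mass


def pair_energy(r: float, sigma_i: float, lambda_i: float, q_i: float,
                sigma_j: float, lambda_j: float, q_j: float,
                lambda_debye: float, eps: float = EPS_AH,
                temperature_K: float = 310.0) -> float:
    """Nonbonded pair energy U_AH + U_DH (kJ/mol) at separation r (nm)."""
    if r <= 0:
        raise ValueError("r must be positive")
    s = 0.5 * (sigma_i + sigma_j)
    l = 0.5 * (lambda_i + lambda_j)
    u = 0.0
    if eps > 0 and r < CUTOFF_AH:
        sr6 = (s / r) ** 6
        ulj = 4 * eps * (sr6**2 - sr6)
        src6 = (s / CUTOFF_AH) ** 6
        shift = l * 4 * eps * (src6**2 - src6)
        if r <= 2 ** (1 / 6) * s:
            u += ulj + (1 - l) * eps - shift
        else:
            u += l * ulj - shift
    if q_i * q_j != 0 and r < CUTOFF_DH:
        eps_r = water_dielectric(temperature_K)
        u += q_i * q_j * _COULOMB / eps_r * math.exp(-r / lambda_debye) / r
    return u


def _pair_tables(sig, lam, q, temperature_K):
    n = len(sig)
    sig2 = (0.5 * (sig[:, None] + sig[None, :])) ** 2
    lamm = 0.5 * (lam[:, None] + lam[None, :])
    eps_r = water_dielectric(temperature_K)
    qq = np.outer(q, q) * _COULOMB / eps_r
    for arr in (sig2, lamm, qq):
        np.fill_diagonal(arr, 0.0)
    return np.ascontiguousarray(sig2), np.ascontiguousarray(lamm), np.ascontiguousarray(qq)


def run_simulation(variant: SpliceVariant | str, protocol: SimProtocol,
                   params: pd.DataFrame | None = None, seed: int = 0,
                   skin: float = 0.3) -> Trajectory:
    """Equilibrate and run production Langevin dynamics for one chain.

    The chain starts as a straight polymer along the box diagonal axis with
    0.38 nm spacing.  Frames are saved every ``frame_interval_ps`` after the
    equilibration period is discarded.  Identical seeds give bit-identical
    trajectories.
    """
    seq = variant.sequence if isinstance(variant, SpliceVariant) else variant
    name = variant.name if isinstance(variant, SpliceVariant) else "custom"
    n = len(seq)
    box = protocol.box_edge(n)
    if box < 0.76 * (n - 1) + 4.0 - 1e-9:
        raise ValueError("box smaller than the protocol formula")
    sig, lam, q, mass = chain_parameters(seq, protocol, params)
    sig2, lamm, qq = _pair_tables(sig, lam, q, protocol.temperature_K)
    if protocol.charges_on and np.any(q != 0.0):
        inv_ld = 1.0 / debye_length(protocol.ionic_strength_mM,
                                    protocol.temperature_K)
    else:
        inv_ld = 0.0

    rng = np.random.default_rng(seed)
    pos = np.zeros((n, 3))
    pos[:, 2] = protocol.bond_length * np.arange(n)
    pos += 0.5 * box - pos.mean(axis=0)
    kbt = KB * protocol.temperature_K
    vel = rng.standard_normal((n, 3)) * np.sqrt(kbt / mass)[:, None]

    dt = protocol.dt_ps
    n_eq = int(round(protocol.equilibration_ps / dt))
    n_prod = int(round(protocol.production_ns * 1000.0 / dt))
    save_every = max(1, int(round(protocol.frame_interval_ps / dt)))
    n_frames = n_prod // save_every

    kernel_seed = int(rng.integers(0, 2**31 - 1))
    if n_eq:
        _run(pos, vel, mass, box, sig2, lamm, qq, protocol.eps_ah, inv_ld,
             protocol.bond_length, protocol.bond_k, dt, protocol.friction_ps,
             kbt, n_eq, n_eq + 1, 0, skin, kernel_seed)
    frames, vels, ok = _run(pos, vel, mass, box, sig2, lamm, qq,
                            protocol.eps_ah, inv_ld, protocol.bond_length,
                            protocol.bond_k, dt, protocol.friction_ps, kbt,
                            n_prod, save_every, n_frames, skin,
                            kernel_seed + 1)
    if not ok:
        raise FloatingPointError(
            f"simulation of {name} diverged (non-finite coordinates) after "
            f"{frames.shape[0]} saved frames; check dt and parameter table")
    times = protocol.equilibration_ps + save_every * dt * np.arange(1, frames.shape[0] + 1)
    return Trajectory(frames, times, seq, name, seed, protocol, vels, mass)


def potential_energy(pos: np.ndarray, sequence: str, protocol: SimProtocol,
                     params: pd.DataFrame | None = None) -> float:
    """Potential energy of a configuration under the simulator's force field."""
    sig, lam, q, _ = chain_parameters(sequence, protocol, params)
    sig2, lamm, qq = _pair_tables(sig, lam, q, protocol.temperature_K)
    inv_ld = (1.0 / debye_length(protocol.ionic_strength_mM, protocol.temperature_K)
              if (protocol.charges_on and np.any(q != 0.0)) else 0.0)
    return _potential_energy(pos, protocol.box_edge(len(sequence)), sig2, lamm,
                             qq, protocol.eps_ah, CUTOFF_AH**2, CUTOFF_DH**2,
                             inv_ld, protocol.bond_length, protocol.bond_k)


def kinetic_temperature(vel: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature via equipartition."""
    ke = 0.5 * float(np.sum(masses[:, None] * vel**2))
    return 2.0 * ke / (3.0 * len(masses) * KB)
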