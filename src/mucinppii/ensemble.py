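"""Synthetic dihedral ensembles and a toy replica-exchange Monte Carlo sampler.

Each residue's (phi, psi) distribution is a weighted mixture of von Mises
basins centred on the named secondary-structure regions (PPII, beta, alphaR,
alphaL).  Glycosylation enters as a configurable weight shift that moves
population out of the compact alphaR basin into PPII — the statistical
signature O-linked GalNAc-Gal glycans imprint on threonine ensembles.

The mixture density also defines an energy landscape
``U(phi, psi) = -kB * T_ref * ln(density)`` on which a small
replica-exchange Monte Carlo sampler runs: per-replica Metropolis
single-angle moves plus periodic neighbour swaps on a geometric temperature
ladder, mirroring the structure of a replica-exchange molecular dynamics
protocol at desk scale.  Residues evolve independently, which keeps the
exact Boltzmann distribution available by direct grid quadrature for
validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e, logsumexp

from .peptide import PeptideModel, PPII_PHI_PSI
from .trajectory import DihedralTrajectory

#: Boltzmann constant, kcal mol^-1 K^-1.
KB_KCAL = 0.0019872041

#: Default basin centres (degrees), each inside its named region rectangle
#: (the alphaR centre sits deep inside the classification band so that
#: basin draws classify to their own region rather than leaking to coil).
BASIN_CENTERS = {
    "PPII": PPII_PHI_PSI,
    "beta": (-135.0, 135.0),
    "alphaR": (-85.0, -80.0),
    "alphaL": (60.0, 45.0),
}

#: Default per-angle von Mises concentration (circular sigma ~ 13 deg).
DEFAULT_KAPPA = 20.0

#: Default basin weights for a non-glycosylated residue: PPII-dominant with
#: minor beta/alphaR/alphaL population.
DEFAULT_WEIGHTS = {"PPII": 0.55, "beta": 0.25, "alphaR": 0.15, "alphaL": 0.05}

#: Prolines: ring closure forbids most of alphaR/alphaL.
PROLINE_WEIGHTS = {"PPII": 0.75, "beta": 0.20, "alphaR": 0.05}

#: Default fraction of basin weight moved alphaR -> PPII on glycosylation
#: (leaves a near-zero alphaR population, the pattern glycosylated
#: threonines show).
DEFAULT_GLYCO_SHIFT = 0.13


@dataclass(frozen=True)
class BasinSpec:
    """One von Mises basin of a residue's (phi, psi) mixture."""

    name: str
    center: tuple[float, float]         # (mu_phi, mu_psi), degrees
    kappa: float                        # per-angle concentration
    weight: float                       # mixture probability

    def __post_init__(self):
        if not self.kappa > 0:
            raise ValueError("kappa must be positive")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must be in [0, 1]")


@dataclass
class ResidueEnsembleSpec:
    """Basin mixture for one residue, with its glycosylation state.

    When ``glycosylated`` is true, ``glyco_weight_shift`` of mixture weight
    is moved from the alphaR basin to the PPII basin before sampling.
    """

    basins: list[BasinSpec]
    glycosylated: bool = False
    glyco_weight_shift: float = DEFAULT_GLYCO_SHIFT

    def __post_init__(self):
        total = sum(b.weight for b in self.basins)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"basin weights sum to {total}, not 1")

    def effective_basins(self) -> list[BasinSpec]:
        """Basins with the glycosylation weight shift applied."""
        if not self.glycosylated or self.glyco_weight_shift == 0.0:
            return list(self.basins)
        names = [b.name for b in self.basins]
        if "alphaR" not in names or "PPII" not in names:
            return list(self.basins)
        shift = self.glyco_weight_shift
        alpha_w = self.basins[names.index("alphaR")].weight
        if shift > alpha_w + 1e-12:
            raise ValueError("glyco_weight_shift exceeds alphaR weight")
        out = []
        for b in self.basins:
            w = b.weight
            if b.name == "alphaR":
                w -= shift
            elif b.name == "PPII":
                w += shift
            out.append(BasinSpec(b.name, b.center, b.kappa, w))
        return out


def default_residue_spec(residue_type: str, glycosylated: bool = False,
                         kappa: float = DEFAULT_KAPPA,
                         glyco_weight_shift: float = DEFAULT_GLYCO_SHIFT
                         ) -> ResidueEnsembleSpec:
    """PPII-dominant mixture spec for one residue of the given type."""
    weights = PROLINE_WEIGHTS if residue_type == "P" else DEFAULT_WEIGHTS
    basins = [BasinSpec(name, BASIN_CENTERS[name], kappa, w)
              for name, w in weights.items()]
    return ResidueEnsembleSpec(basins, glycosylated, glyco_weight_shift)


def peptide_ensemble_specs(model: PeptideModel,
                           kappa: float = DEFAULT_KAPPA,
                           glyco_weight_shift: float = DEFAULT_GLYCO_SHIFT
                           ) -> list[ResidueEnsembleSpec]:
    """Per-residue specs for a peptide model, honouring its glyco sites."""
    mask = model.glycosylated_mask
    return [default_residue_spec(aa, bool(g), kappa, glyco_weight_shift)
            for aa, g in zip(model.sequence, mask)]


@dataclass(frozen=True)
class ReplicaLadder:
    """Temperatures of a replica-exchange ladder (geometric progression)."""

    temperatures: tuple[float, ...]

    def __post_init__(self):
        temps = np.asarray(self.temperatures, dtype=float)
        if temps.size == 0 or np.any(temps <= 0):
            raise ValueError("temperatures must be positive")
        if temps.size > 1:
            if not np.all(np.diff(temps) > 0):
                raise ValueError("temperatures must be strictly increasing")
            ratios = temps[1:] / temps[:-1]
            if np.ptp(ratios) > 1e-9:
                raise ValueError("ladder is not a geometric progression")

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures)

    @property
    def t_min(self) -> float:
        return self.temperatures[0]

    @property
    def t_max(self) -> float:
        return self.temperatures[-1]


def make_ladder(t_min: float, t_max: float, n_replicas: int) -> ReplicaLadder:
    """Geometric temperature ladder: T_k = T_min * (T_max/T_min)^(k/(n-1)).

    Presets matching the mucin-peptide and threonine-tetrapeptide
    replica-exchange protocols are ``make_ladder(300, 455.95, 64)`` and
    ``make_ladder(300, 452.32, 32)``.
    """
    if not (t_max > t_min > 0):
        raise ValueError("need t_max > t_min > 0")
    if n_replicas < 2:
        raise ValueError("need at least 2 replicas")
    k = np.arange(n_replicas)
    temps = t_min * (t_max / t_min) ** (k / (n_replicas - 1))
    temps[0], temps[-1] = t_min, t_max
    return ReplicaLadder(tuple(temps))


@dataclass(frozen=True)
class ExchangeRecord:
    """One attempted swap between ladder neighbours."""

    sweep: int
    pair: tuple[int, int]
    energies: tuple[float, float]       # kcal/mol at attempt time
    accepted: bool

    def __post_init__(self):
        if self.pair[1] != self.pair[0] + 1:
            raise ValueError("exchange pairs must be ladder neighbours")


# ---------------------------------------------------------------------------
# mixture density / energy


def _mixture_params(specs):
    """Stack per-residue basin parameters into arrays padded over basins."""
    n_res = len(specs)
    n_b = max(len(s.effective_basins()) for s in specs)
    logw = np.full((n_res, n_b), -np.inf)
    centers = np.zeros((n_res, n_b, 2))
    kappas = np.full((n_res, n_b), 1.0)
    for r, s in enumerate(specs):
        for b, basin in enumerate(s.effective_basins()):
            logw[r, b] = np.log(basin.weight) if basin.weight > 0 else -np.inf
            centers[r, b] = basin.center
            kappas[r, b] = basin.kappa
    return logw, centers, kappas


def _log_vm(delta_deg, kappa):
    """Log von Mises density (per radian) at angular offset delta (degrees)."""
    d = np.radians(delta_deg)
    # i0e keeps this finite for large kappa: log I0(k) = log i0e(k) + k
    return kappa * (np.cos(d) - 1.0) - np.log(2.0 * np.pi * i0e(kappa))


def mixture_log_density(phi, psi, specs) -> np.ndarray:
    """Log mixture density per residue.

    ``phi``/``psi`` have shape (..., n_residues); returns the same shape.
    The density is periodic in both angles with period 360 degrees.
    """
    logw, centers, kappas = _mixture_params(specs)
    phi = np.asarray(phi, dtype=float)[..., None]
    psi = np.asarray(psi, dtype=float)[..., None]
    lp = (_log_vm(phi - centers[..., 0], kappas)
          + _log_vm(psi - centers[..., 1], kappas))
    return logsumexp(lp + logw, axis=-1)


def mixture_energy(phi, psi, spec, t_ref: float = 300.0) -> np.ndarray:
    """Energy landscape U(phi, psi) = -kB * T_ref * ln(mixture density).

    ``spec`` is a single :class:`ResidueEnsembleSpec`; inputs broadcast.
    Smooth and periodic with period 360 degrees in both angles; minimal at
    the dominant basin centre.  Units kcal/mol (additive constant arbitrary).
    """
    phi = np.asarray(phi, dtype=float)
    logd = mixture_log_density(phi[..., None], np.asarray(psi)[..., None],
                               [spec])[..., 0]
    return -KB_KCAL * t_ref * logd


def residue_energies(phi, psi, specs, t_ref: float = 300.0) -> np.ndarray:
    """Per-residue energies for (..., n_residues) angle arrays."""
    return -KB_KCAL * t_ref * mixture_log_density(phi, psi, specs)


# ---------------------------------------------------------------------------
# direct (i.i.d.) ensemble sampling


def sample_ensemble(specs, n_frames: int, seed,
                    residue_numbers=None, residue_types=None,
                    frame_time_ns: float | None = None) -> DihedralTrajectory:
    """Draw an i.i.d.-per-frame dihedral ensemble from per-residue mixtures.

    For every frame and residue a basin is chosen by weight and phi, psi are
    drawn independently from von Mises distributions about the basin centre.
    A basin with ``kappa = inf`` is treated as a point mass at its centre.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if isinstance(specs, ResidueEnsembleSpec):
        specs = [specs]
    rng = np.random.default_rng(seed)
    n_res = len(specs)
    phi = np.empty((n_frames, n_res))
    psi = np.empty((n_frames, n_res))
    for r, spec in enumerate(specs):
        basins = spec.effective_basins()
        weights = np.array([b.weight for b in basins])
        choice = rng.choice(len(basins), size=n_frames, p=weights)
        for b, basin in enumerate(basins):
            idx = np.nonzero(choice == b)[0]
            if idx.size == 0:
                continue
            mu_phi, mu_psi = np.radians(basin.center)
            if np.isinf(basin.kappa):
                phi[idx, r] = basin.center[0]
                psi[idx, r] = basin.center[1]
            else:
                phi[idx, r] = np.degrees(
                    rng.vonmises(mu_phi, basin.kappa, size=idx.size))
                psi[idx, r] = np.degrees(
                    rng.vonmises(mu_psi, basin.kappa, size=idx.size))
    from .geometry import wrap_degrees
    phi = wrap_degrees(phi)
    psi = wrap_degrees(psi)
    if residue_numbers is None:
        residue_numbers = np.arange(1, n_res + 1)
    if residue_types is None:
        residue_types = ["X"] * n_res
    glyco = np.array([s.glycosylated for s in specs])
    time_ns = (np.arange(n_frames) * frame_time_ns
               if frame_time_ns is not None else None)
    return DihedralTrajectory(phi, psi, residue_numbers, list(residue_types),
                              glyco, time_ns)


# ---------------------------------------------------------------------------
# replica-exchange Monte Carlo


def exchange_probability(u_i: float, u_j: float,
                         t_i: float, t_j: float) -> float:
    """Metropolis acceptance probability for swapping configurations between
    neighbouring replicas: min(1, exp[(1/kB T_i - 1/kB T_j)(U_i - U_j)])."""
    if t_i <= 0 or t_j <= 0:
        raise ValueError("temperatures must be positive")
    delta = (1.0 / (KB_KCAL * t_i) - 1.0 / (KB_KCAL * t_j)) * (u_i - u_j)
    return float(min(1.0, np.exp(min(delta, 0.0)) if delta < 0 else 1.0))


@dataclass
class RemdResult:
    """Output of :func:`remd_run`: one temperature-trajectory per ladder rung
    plus the exchange log."""

    trajectories: list[DihedralTrajectory]   # indexed like ladder rungs
    ladder: ReplicaLadder
    exchange_records: list[ExchangeRecord]
    acceptance_by_pair: dict[tuple[int, int], float] = field(
        default_factory=dict)


def remd_run(specs, ladder: ReplicaLadder, n_sweeps: int,
             exchange_interval: int = 10, proposal_step: float = 25.0,
             seed=0, t_ref: float = 300.0,
             residue_numbers=None, residue_types=None) -> RemdResult:
    """Replica-exchange Metropolis Monte Carlo on the mixture landscape.

    Every sweep updates each residue's phi and psi once per replica with
    wrapped-Gaussian proposals of width ``proposal_step`` degrees (symmetric,
    so no Hastings correction).  Every ``exchange_interval`` sweeps,
    neighbour swaps are attempted on alternating even/odd pairs using
    :func:`exchange_probability`.  Trajectories are recorded per ladder
    temperature (configurations follow swaps), so ``trajectories[0]`` is
    the ensemble at the lowest, analysis temperature.
    """
    if exchange_interval < 1:
        raise ValueError("exchange_interval must be >= 1")
    if proposal_step <= 0:
        raise ValueError("proposal_step must be positive")
    if isinstance(specs, ResidueEnsembleSpec):
        specs = [specs]
    from .geometry import wrap_degrees

    temps = np.asarray(ladder.temperatures)
    n_rep, n_res = len(temps), len(specs)
    betas = 1.0 / (KB_KCAL * temps)

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    # start every replica at its residues' dominant basin centres
    centers = np.array([max(s.effective_basins(),
                            key=lambda b: b.weight).center for s in specs])
    state = np.tile(centers[None], (n_rep, 1, 1)).astype(float)  # (K, R, 2)
    energy = residue_energies(state[..., 0], state[..., 1], specs, t_ref)

    frames = np.empty((n_sweeps, n_rep, n_res, 2))
    records: list[ExchangeRecord] = []
    attempts = {}
    accepts = {}
    parity = 0

    for sweep in range(n_sweeps):
        for angle in (0, 1):
            proposal = state.copy()
            proposal[..., angle] = wrap_degrees(
                state[..., angle]
                + rng.normal(0.0, proposal_step, size=(n_rep, n_res)))
            new_energy = residue_energies(
                proposal[..., 0], proposal[..., 1], specs, t_ref)
            delta = new_energy - energy               # (K, R)
            accept = (np.log(rng.random((n_rep, n_res)))
                      < -betas[:, None] * delta)
            state[accept] = proposal[accept]
            energy = np.where(accept, new_energy, energy)

        if (sweep + 1) % exchange_interval == 0 and n_rep > 1:
            total = energy.sum(axis=1)
            for k in range(parity, n_rep - 1, 2):
                p = exchange_probability(total[k], total[k + 1],
                                         temps[k], temps[k + 1])
                ok = rng.random() < p
                records.append(ExchangeRecord(
                    sweep, (k, k + 1), (float(total[k]), float(total[k + 1])),
                    bool(ok)))
                attempts[(k, k + 1)] = attempts.get((k, k + 1), 0) + 1
                accepts[(k, k + 1)] = accepts.get((k, k + 1), 0) + int(ok)
                if ok:
                    state[[k, k + 1]] = state[[k + 1, k]]
                    energy[[k, k + 1]] = energy[[k + 1, k]]
                    total[[k, k + 1]] = total[[k + 1, k]]
            parity = 1 - parity
        frames[sweep] = state

    glyco = np.array([s.glycosylated for s in specs])
    if residue_numbers is None:
        residue_numbers = np.arange(1, n_res + 1)
    if residue_types is None:
        residue_types = ["X"] * n_res
    trajs = [DihedralTrajectory(frames[:, k, :, 0], frames[:, k, :, 1],
                                residue_numbers, list(residue_types), glyco)
             for k in range(n_rep)]
    rates = {pair: accepts[pair] / attempts[pair] for pair in attempts}
    return RemdResult(trajs, ladder, records, rates)


def boltzmann_bin_probabilities(spec, t_sample: float, n_bins: int,
                                t_ref: float = 300.0,
                                quad_step: float = 2.0) -> np.ndarray:
    """Exact Boltzmann probabilities on an (n_bins x n_bins) histogram grid,
    by brute-force quadrature of exp(-U/kB T) on a fine sub-grid
    (``quad_step`` degrees).  Reference oracle for the sampler."""
    fine = np.arange(-180.0, 180.0, quad_step) + quad_step / 2.0
    fphi, fpsi = np.meshgrid(fine, fine, indexing="ij")
    u = mixture_energy(fphi, fpsi, spec, t_ref)
    w = np.exp(-(u - u.min()) / (KB_KCAL * t_sample))
    per_bin = int(round(360.0 / quad_step / n_bins))
    if per_bin * n_bins != int(360.0 / quad_step):
        raise ValueError("quad grid must subdivide the histogram bins")
    coarse = w.reshape(n_bins, per_bin, n_bins, per_bin).sum(axis=(1, 3))
    return coarse / coarse.sum()
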