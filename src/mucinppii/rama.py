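"""Ramachandran-like free-energy surfaces, secondary-structure region
classification, and per-residue population statistics.

The free-energy surface is the Boltzmann inversion of the binned dihedral
probability distribution relative to its mode,

    dG(phi, psi) = -kB * T * ln[ P(phi, psi) / P_max ],

so the modal bin sits at exactly zero and every other defined bin is
non-negative; empty bins are reported as +inf (unvisited, free energy
undefined by the estimator).

Region classification uses explicit rectangles on the (phi, psi) torus:

    alphaR : -160 < phi <  -20  and -120 < psi <  -50
    beta   : -180 < phi <  -90  and   50 < psi <  240
    PPII   :  -90 < phi <   20  and   50 < psi <  240
    alphaL :   30 < phi <  100  and    0 < psi <   80

with every other point labelled "coil".  Bounds beyond 180 wrap around the
circle (psi < 240 means psi in (50, 180) union [-180, -120)); inequalities
are strict, so angles exactly on a printed bound fall to coil (a
measure-zero convention).

Population uncertainties come from a moving-block bootstrap over frames,
which preserves temporal autocorrelation; group differences are called
significant when the (1 - alpha) bootstrap CI of the difference excludes
zero.  No multiplicity correction is applied across residues.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import KB_KCAL
from .trajectory import DihedralTrajectory

COIL = "coil"

DEFAULT_REGION_BOUNDS = {
    "alphaR": (-160.0, -20.0, -120.0, -50.0),
    "beta": (-180.0, -90.0, 50.0, 240.0),
    "PPII": (-90.0, 20.0, 50.0, 240.0),
    "alphaL": (30.0, 100.0, 0.0, 80.0),
}


@dataclass(frozen=True)
class RegionSet:
    """Named (phi, psi) rectangles on the torus plus the coil catch-all.

    Each region is (phi_lo, phi_hi, psi_lo, psi_hi) in degrees with strict
    inequalities; upper bounds may exceed 180 and then wrap circularly.
    """

    bounds: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGION_BOUNDS))

    def __post_init__(self):
        if COIL in self.bounds:
            raise ValueError("'coil' is the implicit catch-all label")
        for name, (plo, phi_, slo, shi) in self.bounds.items():
            if not (plo < phi_ and slo < shi):
                raise ValueError(f"degenerate bounds for region {name}")

    @property
    def labels(self) -> list[str]:
        return list(self.bounds) + [COIL]

    def check_disjoint(self, step: float = 1.0) -> bool:
        """Exhaustive grid scan of the torus verifying that named regions
        never overlap (classification is then single-valued by
        construction)."""
        grid = np.arange(-180.0, 180.0, step)
        phi, psi = np.meshgrid(grid, grid, indexing="ij")
        hits = np.zeros(phi.shape, dtype=int)
        for name in self.bounds:
            hits += _in_region(phi, psi, self.bounds[name]).astype(int)
        return bool(np.all(hits <= 1))


def _circular_between(value, lo, hi):
    """Strict lo < value < hi on the circle; hi may exceed 180."""
    v = np.asarray(value, dtype=float)
    return ((lo < v) & (v < hi)) | ((lo < v + 360.0) & (v + 360.0 < hi))


def _in_region(phi, psi, bounds):
    plo, phi_hi, slo, shi = bounds
    return (_circular_between(phi, plo, phi_hi)
            & _circular_between(psi, slo, shi))


def classify(phi, psi, regions: RegionSet | None = None):
    """Label (phi, psi) pairs with their secondary-structure region.

    Scalar inputs return a string; array inputs return an object array of
    labels.  Non-finite angles (undefined terminal dihedrals) get ``None``.
    """
    regions = regions or RegionSet()
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    labels = np.full(phi.shape, COIL, dtype=object)
    for name, bounds in regions.bounds.items():
        labels[_in_region(phi, psi, bounds)] = name
    labels[~(np.isfinite(phi) & np.isfinite(psi))] = None
    if labels.ndim == 0:
        return labels.item()
    return labels


def label_codes(traj: DihedralTrajectory,
                regions: RegionSet | None = None):
    """Integer-coded labels (n_frames, n_residues); -1 marks undefined
    terminal angles.  Code order follows ``regions.labels``."""
    regions = regions or RegionSet()
    codes = np.full(traj.phi.shape, len(regions.bounds), dtype=int)  # coil
    for i, name in enumerate(regions.bounds):
        codes[_in_region(traj.phi, traj.psi, regions.bounds[name])] = i
    codes[~(np.isfinite(traj.phi) & np.isfinite(traj.psi))] = -1
    return codes, regions.labels


# ---------------------------------------------------------------------------
# free-energy surface


@dataclass
class FreeEnergySurface:
    """Binned P(phi, psi) and dG(phi, psi) at temperature T.

    ``delta_g`` is +inf on empty bins; exactly 0 at the modal bin.
    """

    phi_edges: np.ndarray
    psi_edges: np.ndarray
    probability: np.ndarray
    delta_g: np.ndarray                  # kcal/mol
    temperature: float
    n_samples: int
    kb: float = KB_KCAL

    @property
    def p_max(self) -> float:
        return float(self.probability.max())

    def to_frame(self) -> pd.DataFrame:
        """Long-format grid: phi_lo, phi_hi, psi_lo, psi_hi, P, dG."""
        n_p, n_s = self.probability.shape
        rows = {
            "phi_lo": np.repeat(self.phi_edges[:-1], n_s),
            "phi_hi": np.repeat(self.phi_edges[1:], n_s),
            "psi_lo": np.tile(self.psi_edges[:-1], n_p),
            "psi_hi": np.tile(self.psi_edges[1:], n_p),
            "P": self.probability.ravel(),
            "dG": self.delta_g.ravel(),
        }
        return pd.DataFrame(rows)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               float_format="%.10g")

    def write_json(self, path) -> None:
        payload = {
            "temperature_K": self.temperature,
            "kB_kcal_per_mol_K": self.kb,
            "n_samples": self.n_samples,
            "phi_edges": self.phi_edges.tolist(),
            "psi_edges": self.psi_edges.tolist(),
            "P": self.probability.tolist(),
            "dG": [[None if not np.isfinite(v) else v for v in row]
                   for row in self.delta_g],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def histogram2d(traj: DihedralTrajectory, n_bins_per_axis: int = 72,
                residues=None):
    """Normalised 2-D histogram of (phi, psi) over [-180, 180)^2.

    Pools all residues and frames (or the given residue-number subset);
    undefined terminal angles are skipped.  Returns (P, phi_edges,
    psi_edges) with P summing to 1.
    """
    if n_bins_per_axis < 2:
        raise ValueError("need at least 2 bins per axis")
    phi, psi = traj.phi, traj.psi
    if residues is not None:
        mask = np.isin(traj.residue_numbers, np.asarray(residues))
        if not mask.any():
            raise ValueError("residue filter matches no residues")
        phi, psi = phi[:, mask], psi[:, mask]
    ok = np.isfinite(phi) & np.isfinite(psi)
    phi, psi = phi[ok], psi[ok]
    if phi.size == 0:
        raise ValueError("no defined (phi, psi) pairs in trajectory")
    edges = np.linspace(-180.0, 180.0, n_bins_per_axis + 1)
    counts, pe, se = np.histogram2d(phi, psi, bins=(edges, edges))
    return counts / counts.sum(), pe, se


def free_energy_surface(probability, phi_edges, psi_edges,
                        temperature: float = 300.0,
                        n_samples: int = 0) -> FreeEnergySurface:
    """Boltzmann-invert a normalised P(phi, psi) grid into a free-energy
    surface relative to the modal bin."""
    p = np.asarray(probability, dtype=float)
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if not p.any():
        raise ValueError("all histogram bins are empty")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probability grid must be normalised")
    p_max = p.max()
    with np.errstate(divide="ignore"):
        dg = -KB_KCAL * temperature * np.log(p / p_max)
    dg[p == 0] = np.inf
    # the modal bin is the zero of the scale by construction
    dg[np.unravel_index(np.argmax(p), p.shape)] = 0.0
    return FreeEnergySurface(np.asarray(phi_edges), np.asarray(psi_edges),
                             p, dg, temperature, n_samples)


def surface_from_trajectory(traj: DihedralTrajectory,
                            n_bins_per_axis: int = 72,
                            temperature: float = 300.0,
                            residues=None) -> FreeEnergySurface:
    """Histogram + Boltzmann inversion in one step."""
    p, pe, se = histogram2d(traj, n_bins_per_axis, residues)
    n = int(np.isfinite(traj.phi).sum()) if residues is None else 0
    return free_energy_surface(p, pe, se, temperature, n_samples=n)


# ---------------------------------------------------------------------------
# per-residue populations


def residue_populations(traj: DihedralTrajectory,
                        regions: RegionSet | None = None) -> pd.DataFrame:
    """Fraction of frames each residue spends in each region.

    Long-format table: residue_number, residue_type, glycosylated, region,
    fraction.  Fractions sum to 1 over regions for every residue with
    defined angles.
    """
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    regions = regions or RegionSet()
    codes, labels = label_codes(traj, regions)
    rows = []
    for r in range(traj.n_residues):
        col = codes[:, r]
        defined = col >= 0
        n_def = int(defined.sum())
        for i, lab in enumerate(labels):
            frac = float((col[defined] == i).mean()) if n_def else np.nan
            rows.append({
                "residue_number": int(traj.residue_numbers[r]),
                "residue_type": traj.residue_types[r],
                "glycosylated": bool(traj.glycosylated[r]),
                "region": lab,
                "fraction": frac,
            })
    return pd.DataFrame(rows)


def _bootstrap_fractions(codes, labels, block_length, n_boot, rng):
    """Moving-block bootstrap replicate fractions,
    shape (n_boot, n_residues, n_labels).

    Blocks of ``block_length`` consecutive frames are drawn with
    replacement; block sums are precomputed with a cumulative sum so each
    replicate is a cheap gather.
    """
    n_frames, n_res = codes.shape
    n_labels = len(labels)
    n_blocks = int(np.ceil(n_frames / block_length))
    onehot = np.zeros((n_frames, n_res, n_labels + 1))
    for i in range(n_labels):
        onehot[..., i] = codes == i
    onehot[..., n_labels] = codes >= 0          # defined-angle counter
    csum = np.concatenate([np.zeros((1, n_res, n_labels + 1)),
                           np.cumsum(onehot, axis=0)])
    starts = np.arange(n_frames - block_length + 1)
    block_sums = csum[starts + block_length] - csum[starts]
    picks = rng.integers(0, len(starts), size=(n_boot, n_blocks))
    out = np.empty((n_boot, n_res, n_labels))
    with np.errstate(invalid="ignore"):
        for b in range(n_boot):
            tot = block_sums[picks[b]].sum(axis=0)
            out[b] = tot[:, :n_labels] / tot[:, n_labels:n_labels + 1]
    return out


def population_ci(traj: DihedralTrajectory, regions: RegionSet | None = None,
                  block_length: int = 10, n_boot: int = 1000, seed=0,
                  level: float = 0.95) -> pd.DataFrame:
    """Per-residue region populations with moving-block bootstrap CIs.

    Blocks of ``block_length`` consecutive frames are resampled with
    replacement so the intervals respect temporal autocorrelation;
    percentile intervals at the given level.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable percentiles")
    if block_length < 1:
        raise ValueError("block_length must be >= 1")
    if block_length >= traj.n_frames:
        raise ValueError("block_length must be smaller than n_frames")
    regions = regions or RegionSet()
    table = residue_populations(traj, regions)
    codes, labels = label_codes(traj, regions)
    rng = np.random.default_rng(seed)
    boots = _bootstrap_fractions(codes, labels, block_length, n_boot, rng)
    alpha = 1.0 - level
    lo = np.nanpercentile(boots, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(boots, 100 * (1 - alpha / 2), axis=0)
    table["ci_low"] = lo.ravel()
    table["ci_high"] = hi.ravel()
    # percentile CIs always bracket the plug-in fraction up to resampling
    # noise; clip to enforce the invariant exactly
    table["ci_low"] = np.minimum(table["ci_low"], table["fraction"])
    table["ci_high"] = np.maximum(table["ci_high"], table["fraction"])
    return table


def compare_populations(traj_a: DihedralTrajectory,
                        traj_b: DihedralTrajectory,
                        regions: RegionSet | None = None,
                        alpha: float = 0.05, block_length: int = 10,
                        n_boot: int = 1000, seed=0) -> pd.DataFrame:
    """Bootstrap comparison of per-residue region populations (B - A).

    Both trajectories are block-bootstrapped independently; the difference
    is significant at level ``alpha`` when its (1 - alpha) percentile CI
    excludes zero.  Typical use: non-glycosylated (A) versus glycosylated
    (B) peptide ensembles, where glycosylated threonines show a PPII gain
    and an alphaR loss.
    """
    if not np.array_equal(traj_a.residue_numbers, traj_b.residue_numbers):
        raise ValueError("trajectories must share residue numbering")
    regions = regions or RegionSet()
    codes_a, labels = label_codes(traj_a, regions)
    codes_b, _ = label_codes(traj_b, regions)
    ss = np.random.SeedSequence(seed)
    rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(2))
    boots_a = _bootstrap_fractions(codes_a, labels, block_length, n_boot,
                                   rng_a)
    boots_b = _bootstrap_fractions(codes_b, labels, block_length, n_boot,
                                   rng_b)
    diff = boots_b - boots_a
    lo = np.nanpercentile(diff, 100 * alpha / 2, axis=0)
    hi = np.nanpercentile(diff, 100 * (1 - alpha / 2), axis=0)
    frac_a = residue_populations(traj_a, regions)["fraction"].to_numpy()
    frac_b = residue_populations(traj_b, regions)["fraction"].to_numpy()
    base = residue_populations(traj_a, regions)[
        ["residue_number", "residue_type", "region"]].copy()
    base["glycosylated_b"] = np.repeat(traj_b.glycosylated,
                                       len(labels))
    base["fraction_a"] = frac_a
    base["fraction_b"] = frac_b
    base["delta"] = frac_b - frac_a
    base["ci_low"] = lo.ravel()
    base["ci_high"] = hi.ravel()
    base["significant"] = (base["ci_low"] > 0) | (base["ci_high"] < 0)
    return base
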