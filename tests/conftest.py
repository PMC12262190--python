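import numpy as np
import pytest

import mucinppii as m
from mucinppii.ensemble import BASIN_CENTERS, BasinSpec, ResidueEnsembleSpec


@pytest.fixture(scope="session")
def mucin_model():
    return m.PeptideModel.mucin_model_peptide(glycosylated=False)


@pytest.fixture(scope="session")
def ppii_backbone(mucin_model):
    """18-mer built with every residue at the canonical PPII dihedrals."""
    return m.build_backbone(mucin_model)


@pytest.fixture(scope="session")
def stationary_trajectory(mucin_model):
    """10,000-frame i.i.d. ensemble of the non-glycosylated 18-mer."""
    specs = m.peptide_ensemble_specs(mucin_model)
    return m.sample_ensemble(specs, 10000, seed=42,
                             residue_numbers=mucin_model.residue_numbers,
                             residue_types=list(mucin_model.sequence))


def two_basin_spec(w_ppii=0.6, kappa=8.0):
    """PPII/beta mixture whose basins are close enough in phi for a
    single-temperature Metropolis chain to hop between them."""
    return ResidueEnsembleSpec([
        BasinSpec("PPII", BASIN_CENTERS["PPII"], kappa, w_ppii),
        BasinSpec("beta", BASIN_CENTERS["beta"], kappa, 1.0 - w_ppii),
    ])


def weighted_spec(weights, kappa=100.0, glycosylated=False,
                  glyco_weight_shift=0.0):
    basins = [BasinSpec(name, BASIN_CENTERS[name], kappa, w)
              for name, w in weights.items()]
    return ResidueEnsembleSpec(basins, glycosylated, glyco_weight_shift)


def region_masses_by_quadrature(spec, regions=None, step=0.25):
    """Exact region probabilities of a residue mixture by fine-grid
    quadrature of the von Mises mixture density (independent of the
    sampling path; region membership uses the classifier's rectangles)."""
    from mucinppii.ensemble import mixture_log_density
    from mucinppii.rama import RegionSet, _in_region, COIL

    regions = regions or RegionSet()
    grid = np.arange(-180.0, 180.0, step) + step / 2.0
    phi, psi = np.meshgrid(grid, grid, indexing="ij")
    dens = np.exp(mixture_log_density(phi[..., None], psi[..., None],
                                      [spec])[..., 0])
    dens /= dens.sum()
    masses = {}
    covered = np.zeros(phi.shape, dtype=bool)
    for name, bounds in regions.bounds.items():
        mask = _in_region(phi, psi, bounds)
        masses[name] = float(dens[mask].sum())
        covered |= mask
    masses[COIL] = float(dens[~covered].sum())
    return masses
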