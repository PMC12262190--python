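# Methods

This note records the model, the default parameters and why they were
chosen, the numerical conventions, and the known limits of the synthetic
generator.

## Model peptide

The model system is an 18-residue peptide spanning two imperfect tandem
repeats of the lubricin mucin domain, PRG4 residues 393–410, sequence
`PKEPAPTTTKEPAPTTPK`. O-glycosylation sites are assigned to every
threonine except Thr401, giving the four sites {399, 400, 407, 408}.
Glycans are represented only as per-residue flags that modify the
conformational ensemble (below); no glycan atoms are built.

Five of the eight residue types in the `KEPAPTTP` repeat unit (P, A, K by
default) are counted as high-PPII-propensity residues, giving 5 of 8
residues per repeat.

## Backbone construction and helix fit

Backbones are built residue by residue from internal coordinates (bond
lengths N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C–O 1.231 Å; bond
angles 111.2°, 116.2°, 121.7°, 120.8°), placing each atom from the three
previous ones by the natural-extension-reference-frame construction.
Backbone torsions are the inputs: φ, ψ per residue, ω fixed at 180°
(trans) unless overridden. Dihedrals are measured with the standard
atan2-based formula under the IUPAC sign convention, reported in
[−180°, 180°). Build-then-measure round trips agree to better than
1e−13 degrees; the dihedral routine was cross-checked against an
independent implementation.

Helix parameters come from a screw-motion fit: the rigid transform
mapping CA(i) → CA(i+1) is estimated by the Kabsch algorithm over all
consecutive CA quadruples, and its rotation angle (twist per residue,
signed by the handedness of the screw) and translation along the axis
(rise) are extracted. Residues per turn is 360°/|twist|. For the ideal
PPII helix at (−75°, 145°) this yields twist −120.24°/residue
(left-handed), rise 3.08 Å, 2.994 residues/turn; the fit was verified
against an independent chord-length equation
d_k² = (k·h)² + 4r²·sin²(k·θ/2) and against a right-handed α-helix
control at (−57°, −47°) (+99.4°, 3.62 residues/turn).

## Synthetic ensemble generator

Each residue draws (φ, ψ) i.i.d. per frame from a mixture of bivariate
von Mises basins (independent φ and ψ components, common concentration
κ per basin):

| basin | centre (φ, ψ) |
|-------|---------------|
| PPII  | (−75°, 145°)  |
| β     | (−135°, 135°) |
| αR    | (−85°, −80°)  |
| αL    | (60°, 45°)    |

Default κ = 20 (circular SD ≈ 13°), chosen so basins are well separated
but have realistic width. Default weights: threonine/serine
PPII 0.55, β 0.25, αR 0.15, αL 0.05; proline PPII 0.75, β 0.20, αR 0.05
(prolines cannot reach αL and their φ is restricted by the ring);
other residues use the threonine weights. These encode the qualitative
propensity ordering (PPII-dominant, β secondary, small helical
populations) rather than any fitted quantity.

Glycosylation moves basin weight from αR into PPII at flagged residues.
The default shift is 0.13, which takes a threonine from
αR ≈ 0.15 → ≈ 0.02 and PPII 0.55 → 0.68 in weight (measured region
populations 0.149 → 0.021 and 0.482 → 0.596 at κ = 20, the difference
being boundary leakage between regions).

Note on the αR centre: a centre near (−63°, −43°) is common in the
literature, but its ψ lies outside the αR classification rectangle used
here (ψ ∈ (−120°, −50°)), which would misroute αR-intended density into
coil. The centre was therefore placed at (−85°, −80°), inside the
rectangle; this is a generator-realism choice, not a claim about the αR
basin position in real proteins.

### Realism and limits

The generator is a stochastic cartoon. Frames are independent (no
kinetics, no autocorrelation unless induced by the Monte Carlo sampler),
residues are independent (no cooperativity or steric coupling along the
chain), basins are symmetric von Mises bumps (real basins are skewed and
correlated in φ–ψ), and glycosylation acts only through a weight shift
(no excluded volume, no glycan–backbone hydrogen bonding). It is
suitable for validating the analysis pipeline and for constructing
ensembles with known ground truth, not for predicting real populations.

## Toy replica-exchange sampler

The mixture density also defines an energy landscape
U(φ, ψ) = −k_B · T_ref · ln ρ(φ, ψ) with T_ref = 300 K and
k_B = 0.0019872041 kcal/mol/K, so Boltzmann sampling at T_ref
reproduces the mixture exactly. Replicas run Metropolis Monte Carlo
with wrapped-Gaussian proposals (default step 25°) on a geometric
temperature ladder T_k = T_min · (T_max/T_min)^(k/(n−1)); presets are
64 replicas over 300–455.95 K and 32 over 300–452.32 K, plus an 8-rung
toy ladder for tests. Every `exchange_interval` sweeps, alternating
even/odd neighbour pairs attempt swaps with acceptance
min(1, exp[(β_i − β_j)(U_i − U_j)]). Correctness is checked against a
quadrature oracle: the exact Boltzmann bin probabilities computed by
2°-grid integration of the landscape, compared by total-variation
distance (long runs reach TV ≈ 0.01–0.03 < 0.05).

The Monte Carlo kinetics are not physical: with κ = 20 the barrier
between ψ-separated basins is deep enough (factor e^−20 in density) that
25° proposals rarely cross it, so multimodal landscapes need either high
temperatures in the ladder or reduced κ to mix. Tests use basins
adjacent in φ (κ = 8) where mixing is demonstrable at CPU-test scale.

## Analysis conventions

**Region classification.** Rectangles on the torus with strict
inequalities; ψ upper bounds of 240° on β and PPII wrap across +180°:
αR (−160, −20) × (−120, −50); β (−180, −90) × (50, 240);
PPII (−90, 20) × (50, 240); αL (30, 100) × (0, 80); everything else,
including exact boundary values, is `coil`. Disjointness and totality
are verified by a 1° grid scan over the full torus.

**Free-energy surface.** (φ, ψ) pooled over residues and frames,
binned 72 × 72 (5° bins) by default;
ΔG = −k_B T ln(P/P_max) at T = 300 K, so the modal bin is exactly 0,
all defined bins are nonnegative, empty bins are +∞ (serialized as
null/blank). The transform is exactly invertible on defined bins and
linear in T by construction.

**Populations and significance.** Per-residue region fractions with
moving-block bootstrap confidence intervals (default block length 10
frames, 1000 replicates, percentile intervals at 95%). Block resampling
is used so the intervals remain valid for autocorrelated (Monte Carlo)
trajectories; for i.i.d. ensembles it is mildly conservative. The
glyco-vs-plain comparison bootstraps both trajectories independently and
calls a difference significant when the (1 − α) percentile interval of
the difference excludes zero (α = 0.05). No multiple-comparison
correction is applied; with 18 residues × 5 regions, a few false
positives per null comparison are expected and observed at close to the
nominal rate.

**Radius of gyration and convergence.** Mass-weighted
R_g = sqrt(Σ m_i |r_i − r_cm|² / Σ m_i) over backbone atoms. The
convergence diagnostic splits the R_g series into two halves, histograms
both on 50 common bins spanning the union of their ranges, and computes
the histogram intersection Σ min(p_i, q_i). Converged means overlap
≥ 0.90 *and* at least two occupied bins — the occupancy guard prevents a
degenerate (constant) series from certifying convergence with a trivial
overlap of 1.

**I/O.** Dihedral tables are TSV with floats written at `%.17g` and read
back with round-trip float parsing, giving bit-exact round trips; angles
already inside [−180°, 180°) are passed through untouched and only
out-of-range values are wrapped. PDB output is fixed-width ATOM records
(backbone N, CA, C, O), multi-model for trajectories, with glyco sites
recorded in REMARK 999; reading uses Biopython.

## Reproducibility

All stochastic entry points take explicit seeds. The pipeline derives
all internal streams from one root seed via `numpy.random.SeedSequence`
spawning (children reduced mod 2³¹), records a hash of its configuration
in the output manifest, and is bit-identical on rerun.

## Limitations

- Populations, shifts, and free energies are properties of the
  configured generator, not measurements of lubricin; only qualitative
  patterns (PPII dominance, the glycosylation direction of effect)
  transfer.
- The peptide is modelled in isolation at ideal geometry: no side
  chains beyond residue-type weights, no solvent, no inter-repeat or
  inter-molecular interactions.
- The Monte Carlo sampler's mixing, not its stationary distribution,
  limits which landscapes it can equilibrate at test scale.
- Bootstrap intervals assume stationarity within a trajectory; the
  convergence diagnostic should be consulted first.
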