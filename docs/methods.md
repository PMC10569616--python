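# Methods

This note documents the models, numerical choices and study conditions
implemented in perfusim, and what the synthetic experiments do and do not
demonstrate about real data.

## Estimation model: dual-compartment porous media

Live tissue is modeled on a regular Cartesian cell grid (cell size `h`,
inactive cells masking the organ outline) as two coexisting porous
compartments. Arterial and venous compartments each satisfy Darcy's law and
incompressibility; a capillary compartment is reduced to a throughput
conductivity `K_c(x)` and porosity `phi_c(x)`, producing the exchange flux

    q(x) = (K_c(x)/mu) (p_a(x) - p_v(x)),

read directly as the local perfusion (rate per bulk volume, 1/s; multiplied
by 6000 for mL/min/100mL). `K_c` carries a nominal m² label: the flux law is
taken literally rather than with a dimensional length-scale correction,
because with the reference value `K_c = 3e-9` and a ~9 kPa compartment
pressure difference it yields perfusion of order tens of mL/min/100mL — the
physiological scale — whereas an `l²`-corrected variant would not.

**Pressure solve.** Five-point finite volumes; face transmissibility is the
harmonic mean of the neighboring cells' directional `K/mu` times the face
geometric factor. Both compartments are assembled into one monolithic sparse
system of `2 N_active` unknowns (the exchange term couples them strongly)
and solved with a sparse direct factorization. Dirichlet pressures are
imposed on designated inlet (artery) and outlet (vein) boundary cells; all
other external faces are no-flow. Connected components of the coupled graph
without any Dirichlet cell raise a diagnostic error naming the component.
Face fluxes below 1e-13 of the maximum are zeroed, which also produces exact
no-flow solutions when `K_c = 0` everywhere.

**Tracer advection.** The scheme obeys a discrete maximum principle, so the
signed flux graph of each compartment is acyclic and concentrations
propagate cell by cell from the most upstream cell (Kahn's algorithm; a
residual cycle after one stricter pruning retry is an error). Each cell acts
as a chain of plug-flow units with lumped transit times

    dtau_a = V phi_a / F_a_up,  dtau_c = phi_c / q,  dtau_v = V phi_v / F_v_dn,

where `F_a_up` is the arterial inflow rate (faces plus boundary) and
`F_v_dn` the venous outflow rate. Capillary inflow is drawn at the arterial
downstream end at the volume-averaged concentration and delivered at the
venular upstream end. Series are shifted by fractional multiples of the
sampling interval with linear interpolation (zero before the first sample);
the volume-averaged concentration is the trailing window mean over
`[t - dtau, t]`, evaluated exactly for the piecewise-linear series. This
pair (shift + trailing mean) is the plug-flow-consistent choice: stored mass
`phi V c_vol` and outflow `F c_dn` then balance the inflow integral exactly
in the continuum limit, and the discrete tracer mass audit closes to well
under 1%. Cells with zero throughput in a compartment are flagged stagnant,
carry zero concentration and infinite transit time, and never enter the
ordering.

The observable per-voxel concentration is
`c_total = phi_a c_a + phi_c c_c + phi_v c_v` (identity enforced to machine
precision).

## Truth model: hybrid-lite network/continuum

The synthetic truth must be structurally richer than the estimation model so
that the inversion faces a genuine model gap. The implementation is a
deliberately simplified ("hybrid-lite") network-continuum coupling:

- **Vessel trees.** Seeded binary trees grown from root nodes on the lower
  domain edge; straight segments, Murray-law radius tapering
  (`r_child = r_parent 2^{-1/3}`), per-generation length ratio 0.75, branch
  half-angle 32° with 6° Gaussian jitter. `depth` counts bifurcation
  generations after the trunk, so a tree has `2^depth` terminals and
  `depth = 0` is a single root-to-terminal edge.
- **Flow.** Poiseuille edge fluxes `Q = pi r^4 dp / (8 mu L)`, node mass
  balance, Dirichlet root pressures (10.6 / 1.60 kPa). Terminal nodes couple
  to the continuum through a uniform disc kernel (support radius
  `eps = 2 mm`) with a single coupling coefficient per terminal; arterial
  and venous continuums exchange with conductance `(K_c/mu) V` per cell,
  and that flux is the TRUE perfusion. `K_c` is zero in vessel-rasterized
  cells, so the true perfusion map vanishes inside vessels by construction.
- **Transport.** Fully implicit backward-Euler upwind advection over network
  edges (well-mixed cylinders), zero-volume mixing nodes and continuum
  cells; the system matrix is an M-matrix, so the scheme is monotone and
  concentrations never exceed the AIF peak. One LU factorization serves all
  time steps. Mass is conserved to round-off.
- **Slab thickness.** The 2D continuum carries a physical slab thickness
  (default 0.5 mm, the stretched-tissue scale) so that 3D network
  conductances and 2D continuum transmissibilities combine consistently.
  Pure-porous results (pressures, q, transit times) are invariant to a
  uniform thickness, so the estimation side is unaffected by this choice.
- **Magnitudes.** The terminal coupling coefficient (4e-15 m³/(Pa·s))
  places most of the arterio-venous pressure drop across the terminal and
  microvascular stages, yielding tissue perfusion of a few to ~15
  mL/min/100mL — the physiological range — rather than the ~50 obtained if
  the full 9 kPa acted directly across the exchange.

The observable fine-grid concentration adds the intravascular contribution
of rasterized vessel segments (edge concentration weighted by the local
vessel volume fraction, capped at 0.8) to the porosity-weighted continuum
concentrations, so vessels are visible in the data as they are in real
acquisitions.

## Observation pipeline

Gamma-variate AIF in peak-normalized form
`c(t) = A ((t-t0)/(ab))^a exp(a - (t-t0)/b)` with defaults `t0 = 5 s`,
`a = 3`, `b = 6 s`, `A = 5 mmol/L` (configuration values, not claims about
any particular acquisition). The fine series is block-averaged (partial
trailing blocks average over available active cells), one-tenth of the time
points (`floor(n_t/10)` of `n_t = 150` seconds) are selected greedily to
maximize `det C_II` of the time-point covariance — first the largest
diagonal entry, then the largest determinant growth via rank-one Cholesky
extension — and independent Gaussian noise with
`sigma = 0.1 × max(coarse data)` is added and clipped at zero. The pipeline
is bit-reproducible under a fixed seed.

## Prior ensemble

Eight fields per member, stacked over active cells: porosities on the linear
scale (means 0.1, 0.1, 1e-4; sds 0.1, 0.1, 1e-5), log-transmissibilities
`ln T = ln(K/mu)` (arterial/venous mean −24.1, capillary mean −10.3, sd 1),
with loose bounds (porosity [0.001, 0.999], `phi_c` [1e-6, 0.1], `ln T`
[−26, −10] arterial/venous and [−26, −8] capillary) applied by clipping —
at draw time and after every update — rather than by reflection or a logit
transform, because the bounds are deliberately loose and clipping is the
simplest testable contract. The capillary prior mean is ~30× the reference
conductivity: recovering perfusion despite a badly misinformed capillary
prior is the point of the exercise.

Fields are stationary Gaussian random fields with a squared-exponential
(Gaussian-variogram) correlation parameterized by the *practical range*
(correlation `exp(-3) ≈ 0.05` at lag = range), since the bare "range" of a
Gaussian variogram is otherwise ambiguous. Sampling uses circulant embedding
on a padded torus with negative-eigenvalue clipping and renormalization
(dense Cholesky for very small grids). Anisotropic range means default to
74 and 60 grid blocks on the reference 128×158 grid and are scaled
proportionally for coarser grids; ranges are redrawn per member (sd one
block) and shared across that member's eight fields — per-field redraws are
a defensible alternative, but per-member draws keep one member's fields
spatially coherent.

In vessel-labeled cells the matching compartment's transmissibility is
overridden with the known Hagen-Poiseuille value `T = D²/(32 mu)` from the
cell's vessel diameter; these entries are re-imposed after every smoother
update (they are known geometry, not estimated parameters), so their
ensemble spread is zero by design. Member `j` is drawn from its own spawned
random stream and is therefore independent of the ensemble size.

## Ensemble smoother

Regularized Levenberg–Marquardt iteration on the ensemble. Anomalies:
`S_m = m_j − mean(m)`, `S_c = c_j − M(mean(m))` (the reference is the
forward run of the mean parameters, one extra simulation per iteration).
With diagonal observation covariance `C_c`, the scaled anomalies
`C_c^{-1/2} S_c` are truncated by SVD at the smallest rank holding 99.9% of
the singular-value sum; the update acts in the retained subspace with gain
factors `w_k / (w_k² + (N−1) gamma)`. Innovations are perturbed with fresh
draws from the data-error distribution each iteration (a flag allows frozen
perturbations). Without truncation and localization this reproduces the
direct ensemble update formula to 1e-10 (verified as an invariant).

**Localization.** Binary taper `Lambda_kl ∈ {0,1}` on the (parameter ×
projected-innovation) gain, recomputed each iteration from the current
ensemble: the pair is retained when the sample correlation magnitude exceeds
the null threshold for spurious correlation at ensemble size N, approximated
on the Fisher scale as `tanh(z_{1−α/2}/sqrt(N−3))` with `α = 0.01`
(config-exposed). The published tapering construction this stands in for is
not fully specified in the open literature; this rule captures its stated
intent — thresholding ensemble-estimated correlations — with a documented,
testable criterion calibrated to the ensemble size.

**Damping schedule and stopping.** `gamma^0 = 1`; a step whose ensemble-
average mismatch (Mahalanobis form `(c_o − c_j)^T C_c^{-1} (c_o − c_j)`)
does not increase is accepted and `gamma ← 0.9 gamma`; otherwise the step is
rejected, the previous ensemble restored, `gamma ← 2 gamma`, and the update
retried (at most 3 consecutive rejections; ties count as acceptance so the
accepted-mismatch sequence is non-increasing by construction). Iterations
stop at a maximum count (10 by default; 5 in the twin experiment) or when
the relative mismatch change between accepted iterations falls below 10%.
The observation vector is ordered time-major over selected time indices,
then row-major over active coarse cells; taper and TSVD factors depend on
this ordering, which is fixed.

## Classical baselines

Maximum slope: `P = max_t dC/dt / max_t AIF`, forward differences, no
smoothing (an optional moving-average smoother exists but is off by
default), valid under the no-venous-outflow assumption. SVD deconvolution:
lower-triangular convolution matrix `A_ik = dt · AIF(t_{i−k})`, TSVD
pseudo-inverse zeroing singular values below a threshold fraction of the
largest (default 0.1 for noisy data; 0.01 recovers noiseless constructions
to ~5%), perfusion as the peak of the recovered flow-scaled residue.
Hematocrit/density correction constants default to 1 and are exposed. The
same global AIF (the injection function, a model input here) is used for
every voxel.

## Study conditions and problem sizes

The reference parameterization: porosities `phi_a = 0.05`, `phi_v = 0.1`,
permeabilities `K_a = 1e-13`, `K_v = 5e-13` m², capillary conductivity
`3e-9` m², viscosity `3e-3 Pa·s`, boundary pressures 10.6/1.60 kPa, 150 s
horizon sampled every 1 s, 15 D-optimal time points, 10% observation noise.
The default truth grid is 256×316 with 2×2 upscaling; the twin experiment
used throughout the tests and the acceptance script runs the desk-scale
variant — 64×80 truth grid (0.5 mm cells, 32×40 mm domain), depth-5 trees,
2×2 upscaling to a 32×40 estimation grid, ensemble size 40, at most 5
iterations, three seeds — chosen as the scaled-down configuration whose
full assimilation loop completes in about half a minute per seed. MAE is
scored over a partition hierarchy from 1×1 to the full per-cell grid, with
region-mean perfusion forced to zero when a region's artery+vein cell
fraction exceeds 50%, and the signed relative error map uses the convention
`100 (P_T − P_E)/P_T` (overestimation negative).

## What the synthetic experiments do and do not show

The phantom exercises the full inverse loop under a real model gap (network
truth vs continuum estimation model, including intravascular signal the
estimation model can only mimic through high-transmissibility channels).
It does not emulate: partial-volume and relaxation effects of MR signal
formation, signal-to-concentration conversion, recirculation of contrast,
vessel-wall leakage, motion, or uncertainty in the AIF and boundary
pressures. Passing twin experiments therefore demonstrates correctness and
robustness of the estimation machinery under controlled conditions — not
clinical accuracy. The posterior-beats-prior margin at fine partition
levels varies between seed realizations; the acceptance comparison is the
median over three seeds, and single small-ensemble runs (as in the reduced
example) can fall short at individual levels.

## Numerical details and degenerate inputs

- Linear solves: SuperLU; pressure-system mass residual is checked at
  1e-8 of total inflow (achieved at round-off in practice).
- Flux-graph pruning at 1e-13 relative; a cycle after stricter pruning is a
  hard error rather than a silent reorder.
- `dtau_c = phi_c/q` with `q = 0` (no local pressure drop) yields an
  infinite capillary transit time: the cell is flagged and carries zero
  capillary concentration rather than a guessed value.
- Greedy D-optimal updates use rank-one Cholesky extension; the covariance
  is validated PSD within 1e-8 of its largest diagonal entry.
- TSVD keeps at least every singular value above 1e-14 of the largest and
  at most the 99.9% energy rank; an all-zero anomaly matrix yields a
  no-op update flagged with rank 0.
- Circulant embedding clips negative torus eigenvalues and renormalizes the
  variance; for grids of ≤1024 cells a dense Cholesky with 1e-10 jitter is
  used instead.
- Region partitions tile the bounding box with remainders absorbed by
  trailing tiles; empty regions (fully inactive) are excluded from MAE and
  logged.

## Known limitations

- The hybrid-lite generator is a stand-in for a fully detailed
  network-continuum model: straight segments, uniform kernels, single
  coupling coefficient, no vessel-wall exchange along edges.
- The taper threshold rule is a documented surrogate for the original
  tapering-matrix construction (see above).
- 2D only; the data model leaves room for a z-dimension but all operations
  are two-dimensional.
- The estimation model has no diffusion/dispersion, compliance or
  extravascular leakage; observed concentration is purely advective.
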