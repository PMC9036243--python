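# Methods

## Model structure

`tdlnpk` implements a minimal PBPK network for IgG antibodies: one plasma
pool, one lumped non-tumor tissue compartment, and one chain per lesion —
tumor interstitium draining through lymphatic vessels into one or more
tumor-draining lymph node (TDLN) compartments. All transcapillary and
lymphatic transport is convective (solvent drag): a fluid flow $L$ across
a barrier with reflection coefficient $\sigma$ moves antibody with
effective clearance $(1-\sigma)L$. There is no diffusive exchange and no
blood-flow limitation; for 150 kDa antibodies, convection dominates
transcapillary transport and this simplification is standard in minimal
PBPK practice.

State variables (all nM): plasma concentration $C_p$; lumped-tissue ISF
concentration; per lesion, total antibody $C_{tot}$ and total target
$R_{tot}$ in the interstitial fluid; the same pair per TDLN branch. The
state ordering is fixed (plasma, tissue, lesions, then nodes in
lesion-major order) so trajectories are reproducible and addressable.

Equations, per lesion $i$ with branches $b$:

- plasma: $V_p\,\dot C_p = -CL_p C_p - \sum_i L_{organ,i}(1-\sigma_{V,i})C_p - L_{tis}(1-\sigma_{V,tis})C_p + \sum_b L_{eff,b}C_{f,b} + L_{tis}(1-\sigma_L)C_{tis}$
- lumped tissue: $V_{tis}\,\dot C_{tis} = L_{tis}(1-\sigma_{V,tis})C_p - L_{tis}(1-\sigma_L)C_{tis}$
- tumor ISF: $V_{ISF,i}\,\dot C_{tot,i} = L_{organ,i}(1-\sigma_{V,i})C_p - \sum_b L_{aff,b}(1-\sigma_L)C_{f,i} - k_{int}C_{b,i}V_{ISF,i}$
- tumor target: $\dot R_{tot,i} = k_{syn,i} - k_{deg}R_{free,i} - k_{int}C_{b,i}$
- TDLN ISF: $V_{ISF,b}\,\dot C_{tot,b} = L_{aff,b}(1-\sigma_L)F_{surv,b}C_{f,i} - L_{eff,b}C_{f,b} - k_{int}C_{b,b}V_{ISF,b}$, with no vascular entry term because $\sigma_{V,TDLN}=1$ (high endothelial venules reject convective antibody entry); the node target equation mirrors the tumor's with baseline $R_{02}$.

Free/bound partitions come from the quasi-equilibrium binding layer at
every right-hand-side evaluation (below). Only free antibody enters
lymph; bound antibody is cell-surface-attached and is eliminated by
complex internalization, not by washout. Efferent lymph likewise carries
free antibody only.

**Fluid bookkeeping.** The tabulated organ lymph flow feeding the tumor
(0.001–0.082 L/h) exceeds the afferent node flow (0.004 L/h). The model
treats each flow as an independent solvent-drag clearance and does not
track fluid volume: the excess interstitial filtrate is implicitly
reabsorbed without carrying antibody. Antibody mass, not fluid, is the
conserved quantity — with clearance, internalization and transit loss
disabled the ODEs conserve total antibody to solver precision, and the
test suite checks this for every registered study.

## Quasi-equilibrium binding

Antibody–target association/dissociation is fast relative to turnover
($k_{deg} = k_{int} = 0.01\,h^{-1}$), so binding is solved algebraically:
$C_b$ is the smaller root of $(C_{tot}-C_b)(R_{tot}-C_b) = K_d C_b$,
evaluated in the cancellation-free form
$C_b = 2\,C_{tot}R_{tot}\,/\,(b + \sqrt{b^2 - 4C_{tot}R_{tot}})$ with
$b = C_{tot}+R_{tot}+K_d$. A companion explicit-kinetics model
(`tdlnpk.kinetics`, separate free/bound/complex states, $k_{on}$ given,
$k_{off}=k_{on}K_d$) exists purely as a validation reference: at
$k_{on}=100\,nM^{-1}h^{-1}$ the two agree within 2 % on total antibody
over two weeks for the renal parameter set. Degradation acts on free
target only and internalization on complex only; with this split the
baseline $R_0$ is a fixed point of the turnover equations when
$k_{syn}=k_{deg}R_0$, which is how synthesis rates are derived.

`StudyParameterSet.replace` re-derives $k_{syn}$ from the (possibly new)
baseline unless a value is pinned explicitly. Pinning exists for
one-at-a-time sensitivity sweeps of $k_{deg}$, where synthesis must stay
at its reference value rather than silently co-varying.

## Lymphatic transit survival

The fraction of afferent antibody flux surviving the PT→TDLN path is an
empirical, organ-specific quantity. The default "power_shape" strategy
models transit as $n_{ref}/d_{ln}$ independent pinocytosis events, each
removing a fraction $p\,(1-f_{FcRn})$ of passing antibody, where
$f_{FcRn} = [FcRn]/([FcRn]+K_{d,FcRn})$ is the endosomal FcRn-bound
(salvaged) fraction:

$F_{surv} = \left(1 - p\,(1-f_{FcRn})\right)^{n_{ref}/d_{ln}}$

Defaults: $p = 0.1$ per event, $n_{ref} = 100$, $[FcRn] = 40\,\mu M$;
$d_{ln}$ is the tabulated per-study shape factor (19–63). Survival is
strictly increasing in $d_{ln}$ and strictly decreasing in
$K_{d,FcRn}$, the directions the sensitivity analysis expects; salvaged
antibody continues downstream rather than returning to plasma, since
FcRn recycling releases intact IgG back into the vessel lumen. The
functional form is registered under a strategy name and alternatives can
be plugged in without touching the ODE core. Mechanistic endosomal
pH-dependent FcRn kinetics are deliberately out of scope.

## Parameters

| parameter | meaning | unit | default / range |
|---|---|---|---|
| $\sigma_V$ | tumor vascular reflection coefficient | – | 0.65–0.97 per study |
| $\sigma_L$ | lymphatic reflection coefficient | – | 0.2 (all studies) |
| $L_{organ}$ | lymph flow feeding the tumor (0.2 % of organ blood flow) | L/h | 0.001–0.082 |
| $L_{aff}, L_{eff}$ | afferent / efferent node lymph flow | L/h | 0.004 |
| $V_{ISF,PT}$ | tumor interstitial volume (20 % of tumor volume) | L | 0.001–0.265 |
| $V_{ISF,TDLN}$ | node interstitial volume (20 % of an average node) | L | 5.84e-5 |
| $V_p$ | plasma volume | L | 5 (7 esophagogastric) |
| $CL_p$ | plasma clearance | L/h | 0.0083–0.075 |
| $R_{01}, R_{02}$ | baseline target concentration, PT / TDLN | nM | 1–1000 / 1–1000 |
| $K_d$ | antibody–target affinity | nM | 0.058–5 |
| $k_{deg}, k_{int}$ | target degradation / complex internalization | 1/h | 0.01 |
| $K_{d,FcRn}$ | antibody–FcRn affinity | nM | 774 or 2400 |
| $d_{ln}$ | transit shape factor | – | 19–63 |

The lumped-tissue compartment has no published counterpart for these
studies; defaults ($L_{tis}=0.12$ L/h, $\sigma_{V,tis}=0.95$,
$V_{ISF,tis}=8.4$ L) are standard minimal-PBPK whole-body values, are
configurable, and only plasma/PT/TDLN outputs are ever compared to data.

## SUV output

Immuno-PET reports standardized uptake values. The model's tissue region
of interest is a two-component signal — interstitial fraction
$f_{isf}=0.2$ (the same 20 % ISF convention used for the volumes) plus
vascular fraction $f_{vasc}=0.05$ — converted at 150 kDa and unit tissue
density: $SUV = (f_{isf}C_{tot} + f_{vasc}C_p)\,MW\cdot10^{-6} /
(\text{dose}_{mg}/BW_{kg})$. Plasma SUV uses $f_{vasc}=1$. This is a
mean-type SUV; no partial-volume or max-voxel correction is attempted,
and per-study scale factors (`suv_scale`) default to 1. Tracer protein
doses are study-specific and unpublished; the package default is a 10 mg
IV bolus in a 70 kg subject, and SUV is dose-invariant whenever target
binding is linear. Radioisotope physics (decay, residualizing signal) is
out of scope.

## Calibration

`tdlnpk.calibrate.fit` runs box-constrained trust-region-reflective
least squares (SciPy) on the SUV scale. Default free set
{$\sigma_V$, $R_{01}$, $R_{02}$, $d_{ln}$, $CL_p$} with registry values
as initials and physical boxes ($\sigma_V \in [0,1]$, positive ranges
elsewhere); parameters with high uncertainty should stay fixed at their
registry values. Weighting is inverse-SD when dispersions are present
(unit weight where missing or zero), with unweighted and
inverse-prediction options. A 5-point Latin-hypercube multistart with a
fixed seed (20220414) guards against poor basins while keeping fits
deterministic. Diagnostics: estimates landing on a bound are flagged; a
±20 % finite-difference probe around the optimum flags parameters the
objective is locally insensitive to, so flat directions (e.g. node-side
parameters against plasma-only data) surface as `identifiable=False`
rather than as spurious point estimates. Population/mixed-effects and
Bayesian estimation are out of scope.

## Scenarios

- **Metastasis**: extra lesion chains share the plasma pool; a
  metastasis takes the physiology of its organ of residence (e.g. a lung
  metastasis uses the NSCLC row) with its own target densities and
  transit factor.
- **Surgery**: $R_{01}=0$ (the tumor-bed compartment persists, per the
  resection parameterization) and $L_{organ}, L_{aff}$ scaled by
  $1-\text{reduction}$; 50 % and 80 % reductions bracket
  surgery-induced lymphedema.
- **Inflammation**: the PT efflux splits across several TDLN branches in
  proportion to their afferent flows. Compressed intratumoral branches
  default to 0.01× flow and hyperperfused peritumoral branches to 2× —
  the literature says "compressed" and "considerably increased" without
  numbers, so these are exposed, configurable defaults. Tumor-positive
  branches carry the study's $R_{02}$; tumor-negative branches carry
  none.

## Sensitivity analysis

Local, one-at-a-time sweeps over an 11-point fold grid
(0.1–100×, containing 1.0 as the reference row). Reflection coefficients
use restricted ranges — $\sigma_V$ absolute in [0.01, 1.25] and
$\sigma_L$ folds in [0.1, 5] — with any value above the physical ceiling
of 1 clamped and the clamp recorded in the output table (grid values
above 1 are nonphysical, so they are evaluated at 1 rather than
simulated as-is). The $R_{01}/R_{02}$ ratio is swept by scaling
$R_{01}$ with $R_{02}$ held fixed. The sensitivity score is
$\max_g |AUC_g - AUC_{ref}|/AUC_{ref}$ on tissue concentration AUC; the
insensitivity threshold of 5 % is a repo convention and configurable.
Global methods (Sobol, Morris) are out of scope. Note that for parameter
sets where the dose and tumor target concentrations are comparable (the
renal study: 13.3 nM initial plasma vs $R_{01}=10$ nM), $k_{deg}$ is
*not* insensitive at the extreme 100× fold even with synthesis pinned,
because degradation then outruns antibody delivery and removes the
bound-antibody component of the signal; the acceptance suite computes
this score honestly.

## Synthetic data generator

Emulates sparse immuno-PET sampling: default three scan days (48, 96,
168 h), plasma/PT/TDLN, six subjects, multiplicative lognormal noise at
CV = 0.2 — SUV is positive and reported SDs in these studies are large
and grow with the mean, which a lognormal matches; additive Gaussian is
available. Deviates are mean-centred ($e^{\sigma z - \sigma^2/2}$,
$\sigma^2=\ln(1+CV^2)$) so different seeds agree in expectation;
generation is bit-reproducible per seed; subjects collapse to the
mean ± SD schema the calibration module reads. What it does **not**
emulate: digitization error, inter-study SUV-variant differences
(SUVmean vs SUVmax), isotope residualization, dropout, or correlated
intra-subject noise — so passing recovery tests show estimator
self-consistency under the stated noise model, not robustness to every
artefact of real immuno-PET data.

## Numerical choices

LSODA (stiff-capable) with rtol $10^{-8}$, atol $10^{-10}$ nM
everywhere; states are clipped at zero before each binding solve
(negative excursions are bounded by the solver tolerance and the
non-negativity of the vector field at the boundary); non-finite states
abort with a snapshot-carrying error. Trajectory AUCs are trapezoidal;
halving the default 2 h output grid moves them by well under 0.1 %.
Simulation horizons are two weeks (336 h) for study comparisons — the
span immuno-PET studies actually image — and up to 1000 h in the
long-horizon stability tests; problem sizes in the test and acceptance
runs (169-point grids, 50 refit replicates) were chosen as the smallest
that make the checked quantities grid- and replicate-stable.

## Known limitations

- The transit-survival form and the SUV composition are empirical
  choices — the simplest forms consistent with the known physiology and
  the expected monotonicities — not mechanistically derived; each is
  isolated behind a replaceable unit (the RHS, the strategy registry,
  `SUVOptions`) so alternative formulations can be swapped in without
  touching the rest of the package.
- Two-pore extravasation, endosomal FcRn trafficking, blood-flow-limited
  organs, dynamic tumor growth, time-varying flows and any
  pharmacodynamics (T-cell priming) are out of scope.
- The model predicts population-average gradients; per-study SUV-variant
  mismatches mean it should be read as a comparative/qualitative tool
  rather than a patient-specific predictor.
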