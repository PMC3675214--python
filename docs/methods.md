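# Methods

## Restricted mutation space

The design space is all derivatives of a reference peptide (default
RGTFEGKF, the experimentally validated groove binder) in which each residue
is replaced only by members of its own chemical group:

| group | residues |
|---|---|
| nonpolar aliphatic | G A V P L I M |
| aromatic | F Y W |
| polar uncharged | S T C N Q |
| negatively charged | D E |
| positively charged | K H R |

plus a directional exclusion list, by default {G→M} (the methionine
derivative of the reference binder is known to be inactive; the reverse
substitution M→G is not excluded because nothing argues against it).
Kyte–Doolittle hydropathy indices are attached to the same table and drive
the surrogate scorer. Under these rules an 8-mer has
Σᵢ (|group(i)| − 1 − exclusions(i)) single mutants — 23 for RGTFEGKF —
instead of 8 × 19 = 152 unrestricted ones, and the full space shrinks from
20⁸. Histidine sits in the positively charged group; there is no
pH-dependent handling. Positions are 1-based everywhere serialized, written
`<from><position><to>` ("G2V").

## Library search

`run_search` implements a recursive combine-score-accept procedure:

1. Score the reference and every allowed single mutant with the primary
   scorer. Keep strict improvements (ties rejected, keeping the library
   minimal); these n₁ members initiate the Inhibitor Candidate Library.
2. Each cycle takes a snapshot of current members and forms the unions of
   every unordered pair of member mutation sets. A union is viable only if
   its positions are distinct, it stays within the stacking cap
   (default 4), and it is strictly larger than both parents. Novel viable
   sequences are scored; strict improvements are appended with full
   provenance (parent pair, cycle index). Two cycles therefore reach
   4-point mutants: cycle 1 makes doubles from singles, cycle 2 makes
   triples (1+2) and quadruples (2+2).
3. Stop at the cycle limit (default 2), when a cycle adds nothing, or when
   a target size is reached.
4. `rescore_and_filter` applies a second, independent scorer and keeps
   members that strictly beat the reference under it too, sorted best-first
   (ties broken by sequence for determinism).

Reachability is deliberately pairwise — a k-point candidate exists only if
two current members produce it — which is *not* equivalent to enumerating
all subsets of accepted singles; with interaction terms in the scorer the
two differ, and the test suite checks the engine against an independently
coded brute-force recursion with the same rules. Within a cycle, members
accepted mid-cycle do not pair until the next cycle (fixed-snapshot
semantics). Scores are cached per sequence, so a sequence reachable through
several parent pairs is scored once, and re-derivations only extend its
provenance. Because scorers are pure, these caches affect cost, never
membership.

Scorer polarity is explicit metadata (`higher` for docking-fitness-like
scores, `lower` for free-energy-like scores in kJ/mol) rather than a sign
convention. A veto hook on candidates models the manual pose-inspection
step of docking workflows (discard candidates that miss the groove);
default accepts everything.

The surrogate groove scorer — w_c·Σ_contact h(aaᵢ) − w_s·Σ_solvent h(aaⱼ)
over the alternating contact/solvent faces, h = Kyte–Doolittle — exists so
the full pipeline runs with no proprietary docking software. It is additive
and non-physical by construction and is not claimed to reproduce docking
rankings.

## Work, Jarzynski estimator, stiff-spring PMF

A constant-velocity pulling protocol drags a harmonic guide (spring
constant k, units kcal/(mol·Å²); a printed value of "kcal/(mol·Å)" for a
harmonic spring is interpreted as per-Å² since a harmonic constant must
carry inverse length squared) along the reaction coordinate ξ with
λ(t) = λ₀ + v·t. Per trajectory the external work is

    W(t) = v ∫₀ᵗ k (λ(t′) − ξ(t′)) dt′ ,

evaluated by trapezoidal quadrature on the recorded sample times (exact for
constant spring extension; a refinement test covers sampling-interval
sensitivity). Work values are interpolated linearly onto a common λ grid
and anchored to zero at the grid start before combining.

Jarzynski's equality, exp(−βΔA) = ⟨exp(−βW)⟩, gives the free-energy
profile; the exponential average is computed as a shifted log-sum-exp
(subtracting the minimum work) so large β·W cannot underflow. The
second-order cumulant estimator mean(W) − β·var(W)/2 (unbiased variance) is
provided as a lower-variance companion — exact for Gaussian work — and
trajectory-level bootstrap resampling (seeded, percentile intervals)
quantifies uncertainty.

The PMF is read off at leading order of the stiff-spring approximation,
Φ(ξ = λ) = ΔA(λ) − ΔA(λ₀); the spring constant is recorded on the profile
so users can judge stiffness validity. The 1/k correction
(ξ = λ − ΔA′/k, Φ = ΔA − ΔA′²/2k) is available behind an explicit flag,
default off, since at the stiffnesses used here it is far below the
statistical error.

Constants and units: k_B = 0.0019872041 kcal/(mol·K), T defaults to 310 K
(β ≈ 1.624 mol/kcal); energies kcal/mol, distances Å, time ns. kJ/mol
inputs convert via ×0.239006.

## Synthetic pulling ensembles

`synthetic_smd` integrates an overdamped Langevin particle in a known 1-D
potential U, coupled to the moving guide:

    dξ = [−U′(ξ) − k(ξ − λ(t))]/γ dt + √(2 dt/(β γ)) η ,  η ~ N(0,1)

(Euler–Maruyama, stability guard dt·(k + max U″)/γ < 0.1). Potentials:
flat, harmonic, double-well (quartic), piecewise-linear. One master seed is
split into per-trajectory streams by `SeedSequence.spawn`, so ensembles are
bit-reproducible. Initial conditions are drawn from equilibrium in the
guide well (or fixed at λ₀).

**Default validation scenario.** Harmonic potential a = 1 kcal/(mol·Å²)
centered mid-range, guide k = 50 kcal/(mol·Å²), v = 1 Å/ns,
γ = 1 kcal·ns/(mol·Å²), T = 310 K, M = 50 trajectories, dt = 5·10⁻⁴ ns,
samples every 10 steps, pulled over 1 Å. The pulled distance is the one
deliberately chosen quantity: for this model the mean dissipated work is
≈ γ·v·L and near equilibrium the work spread obeys σ_W² ≈ 2·W_diss/β, while
an M-sample exponential average is only trustworthy for β·σ_W ≲ 2. With γ,
v and M fixed as above, L = 1 Å puts the scenario inside that convergence
envelope (β·σ_W ≈ 1.3 measured), i.e. in the regime where the quasi-static
and stiff-spring assumptions demonstrably hold rather than hold in name.
Under these conditions the recovered Φ deviates from the analytic potential
by ≈ 0.1–0.5 kcal/mol (max over the range; mean ≈ 0.3 across seeds), and
halving v reduces the error, as it must when dissipation shrinks.

**What the generator does and does not emulate.** It reproduces the
statistical structure of constant-velocity pulling data — guide schedule,
fluctuating spring force, dissipation growing with pulling speed,
trajectory-to-trajectory work spread — so it exercises every estimator code
path with a known answer. It does not emulate a solvated peptide–fibril
complex: no inertia, no multidimensional coordinate, no slow orthogonal
relaxation, no force-field realism. Passing the recovery test therefore
validates the estimator chain (work quadrature → exponential average →
stiff-spring mapping), not the accuracy of any particular molecular
system's PMF.

## Numerical and design choices

- Strict-inequality acceptance everywhere a score is compared; ties reject.
- Trapezoidal work quadrature on recorded times; no resampling before
  integration.
- Linear interpolation onto the λ grid; grids must lie inside the recorded
  pulling range.
- Exponential averages via shifted log-sum-exp; bootstrap percentile
  intervals at 95 % by default.
- Directional exclusions; self-substitutions never enumerated.
- Search determinism: enumeration order (position, then alphabetical
  target), insertion-ordered members, lexicographic tie-breaks — identical
  seeds and inputs give byte-identical outputs.
- Degenerate inputs fail loudly with typed errors (empty ensembles,
  non-monotone time, conflicting mutations, unknown residues, unstable
  time steps), mapped to exit code 2 in the CLI where they are user input.

## Limitations

- The surrogate scorer is a stand-in; library contents under it carry no
  physical meaning. Real use requires externally computed score tables.
- Only unidirectional (pulling) work is supported — no Crooks/BAR, no
  umbrella/WHAM.
- The leading-order stiff-spring mapping biases the PMF where the profile
  curves on the scale of the guide width; the flag-gated 1/k correction
  mitigates but does not remove this.
- The Jarzynski exponential average is biased low at small M when
  dissipation is large; the cumulant estimator helps only while work stays
  near-Gaussian. The validation scenario is sized to stay in the regime
  where both are reliable, and results outside that regime should be
  treated as lower bounds on barrier heights.
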