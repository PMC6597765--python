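# Methods

## The model in brief

`coemerge` quantifies how co-infections shape the fate of a mutant pathogen
strain in two coupled layers.

**Within-host layer.** A wild-type strain `W` and a mutant strain `M`
replicate exponentially and are killed by a shared immune response `I`:

    dW/dt = rw·W − k·W·I
    dM/dt = rm·M − k·M·I
    dI/dt = s·I·(W+M)/(A+W+M)

Transmission occurs at rate `λ(t) = max(0, log10[(1+x·δM)(W+zM)])`, where
`z` is the mutant's relative transmissibility (selfish advantage), `x` the
mutant's boost to whole-host infectivity (unselfish advantage, active only
when the mutant is present, `δM = 1{m0>0}`), and the clamp encodes that
densities at the clearance scale transmit nothing. Pathology is
`α(t) = W + v·M` with `v` the mutant's relative virulence. The infection
ends at the first of: pathology crossing the lethal threshold `Φ`, total
density falling below the clearance threshold `Ω`, or the horizon `t_max`.
Total transmission `Λ = ∫₀^τ λ dt` is proportional to the infection's R₀.

A transmission event founds the next infection with a bottleneck of `n`
particles, each mutant independently with probability
`θ(t) = zM/(W+zM)`. Averaging over the infection gives the
co-transmission probability and the mutant share of single-strain events:

    c = (1/Λc) ∫ (1 − θⁿ − (1−θ)ⁿ) λ dt
    b = (1/((1−c)Λc)) ∫ θⁿ λ dt

and the dominance of the mutant phenotype is
`d = (Λc − Λw)/(Λm − Λw)` — the degree to which a co-infection transmits
like the mutant rather than the wild-type. For identical strains at equal
inocula, `θ ≡ 1/2` and `c = 1 − (1/2)^(n−1)` in closed form; this is the
main internal validity check of the quadrature machinery.

**Between-host layer.** A discrete-generation three-type branching process
over wild-type infections, mutant infections and co-infections. Offspring
counts are Poisson: mean `Rw` for W, `Rm` for M; a co-infection has mean
`Rc = d·Rm + (1−d)·Rw` (clamped at zero) split as `Rcc = c·Rc`,
`Rcm = (1−c)·b·Rc`, `Rcw = (1−c)(1−b)·Rc`. Mutation (probability `μ1`)
re-classifies a wild-type infection as a co-infection before it
reproduces; reversion (`μ2`) does the same to a mutant infection. The PGF
map is therefore

    fW(s) = (1−μ1)·exp(Rw(sW−1)) + μ1·fC(s)
    fM(s) = (1−μ2)·exp(Rm(sM−1)) + μ2·fC(s)
    fC(s) = exp(Rcw(sW−1) + Rcm(sM−1) + Rcc(sC−1))

whose minimal fixed point is the extinction probability vector;
emergence = 1 − extinction, reported by default for a chain started from a
single wild-type infection. The mutation term uses `fC` rather than a
single-type PGF because a mutated infection carries both strains and
reproduces exactly as a co-infection — the only reading consistent with the
offspring-mean decomposition above.

The **linkage pipeline** closes the loop: for each phenotype value it sets
`Rm = Rw·Λm/Λw`, takes `d` and the bottleneck's `(b, c)` from the
within-host scan, and evaluates emergence. The identity
`d·Rm + (1−d)·Rw = Rw·Λc/Λw` holds algebraically and is asserted on every
row as a pipeline self-check.

## Default parameters

Within-host defaults: `rw = rm = 1`, `k = 1e-4`, `s = 0.8`, `A = 1e3`,
`x = 0`, `z = 1`, `v = 1`, `Φ = 1e8`, `Ω = 1` (all rates per unit time,
densities in arbitrary units). Five mutant phenotypes are scanned with
scenario-specific lethal thresholds: increased growth (`1 ≤ rm ≤ 2`,
`Φ = 1e12`), decreased growth (`0 ≤ rm ≤ 1`, `Φ = 1e6`), decreased
virulence (`0 ≤ v ≤ 1`, `Φ = 1e7`), increased transmissibility
(`1 ≤ z ≤ 4`, `Φ = 1e8`), increased host infectivity (`0 ≤ x ≤ 4`,
`Φ = 1e8`).

Branching defaults: `Rw = 0.75`, `Rm = 1.5`, `b = c = 0.5`,
`μ1 = μ2 = 0.01` (the reference point for single-parameter sweeps); the
linkage pipeline uses `Rw = 0.9`, `μ1 = μ2 = 0.01`. Sensitivity ranges:
`Rw ∈ [0,1]`, `Rm ∈ [1,4]`, `d ∈ [0,1]` (or `[−0.5, 1.5]` when exploring
under-/overdominance), `c, b, μ1, μ2 ∈ [0,1]`.

## Design choices

**Inocula.** Initial conditions are not part of the printed model and are a
package decision: single infections start at the clearance scale
(`w0 = 1 = Ω` or `m0 = 1`) with `i0 = 1` so immune growth can act.
Co-infections split the *same total inoculum* equally (`w0 = m0 = 0.5`)
rather than doubling it. This makes the co-infection exactly comparable to
a single infection: for a mutant differing only in transmission efficiency
(`x > 0`), the co-infection total obeys the same ODE as the mutant-only
density, so `Λc = Λm` holds to integrator precision and the phenotype is
completely dominant, as it should be on symmetry grounds. With a doubled
inoculum the co-infection trajectory is a time-shifted copy of the single
infection and the comparison picks up a spurious ~0.5% offset.

**Event handling.** LSODA with `rtol = 1e-8`, `atol = 1e-10`; thresholds
span eight-plus orders of magnitude so a stiff-capable method is required.
Termination events are located by root-finding: pathology as an upward
crossing of `α − Φ`; clearance as a strict downward crossing of the total
density through `Ω·(1 − 1e-12)`. The infinitesimal inward shift means an
inoculum starting exactly at `Ω` and growing is not terminated at `t = 0`,
while a non-replicating inoculum is cleared immediately. `Λ(t)` and the
`b`/`c` numerators for every requested bottleneck are integrated as
auxiliary ODE states, so the reported integrals are exact at the event
time rather than re-interpolated. Runs that reach `t_max` (default 10,000)
are flagged `horizon` with a warning rather than silently truncated.

**Dominance at near-neutral phenotypes.** `d` is a ratio of two quantities
that both vanish as the mutant approaches the wild-type, with the
structural limit `d →` (mutant share of the co-infection inoculum) = 1/2:
to first order a perturbation of `rm` (or `z`) enters the co-infection's
transmission with weight `θ ≈ 1/2` but the mutant-only infection with
weight 1. Dominance classifications of a phenotype are therefore
meaningful only away from the neutral point; exactly-neutral grid values
are reported as missing rather than 0/0.

**Extinction solver.** Functional iteration `q ← f(q)` from the zero
vector converges monotonically to the minimal fixed point, but only
sublinearly at criticality (error ~ 2/k after k steps). The solver
therefore first applies the classical mean-matrix criterion: for each
start type it computes the spectral radius of the mean offspring matrix
restricted to the types reachable from it (mutation folded in), and pins
the extinction probability to exactly 1 when that radius is ≤ 1 (the
offspring laws here are never the degenerate always-one-child case).
Remaining components are iterated to sup-norm tolerance `1e-12` with an
iteration cap of 1e6; non-convergence is flagged, never silently accepted.

**Monte-Carlo chain simulator.** An independent check on the PGF algebra,
vectorized across chains. A chain emerges when total infections reach
1,000 (a supercritical chain that large escapes extinction with
overwhelming probability), goes extinct at zero, and is censored at 200
generations. Censored chains are counted as emerged and the censoring
fraction reported: the true emergence probability is thus bracketed
between the strict-emergence fraction and the reported estimate. At
near-critical parameters lingering chains make this censoring bias the
dominant error term — comparisons against the analytic solution should use
the bracket, not the point estimate alone.

**Sensitivity machinery.** Latin hypercube sampling uses
`scipy.stats.qmc.LatinHypercube` (uniform draw within each of N
equal-width strata, independent permutations across parameters; N = 500
in the standard runs). PRCC is the classic residual-on-ranks construction:
rank-transform every column (average ranks on ties), regress the target
parameter's ranks and the response's ranks on all other parameters' ranks,
and correlate the residuals; it is invariant under strictly monotone
transforms of any column and is cross-checked in the test suite against an
independent partial-correlation implementation. Confidence intervals are
percentile bootstrap over design rows (B = 500, 95%).

## What the tests show — and what they do not

The test suite validates the machinery against closed forms (neutral
co-transmission, single-type Poisson extinction, criticality boundaries),
against independent recomputation (trapezoid quadrature, per-individual
chain simulation, partial-correlation oracle), and against the framework's
qualitative predictions (dominance raises emergence; co-transmission helps
dominant and hurts recessive mutants; recessive phenotypes need tight
bottlenecks). All inputs are generated by the models themselves — there is
no empirical data, so passing tests demonstrate internal consistency of
the framework and reproducibility of its predictions, not fit to any real
host–pathogen system. The within-host model deliberately omits
within-host stochasticity, explicit immune-compartment structure and more
than two strains.

Standard problem sizes keep every result reproducible on a single CPU:
phenotype scans use 21–50 grid points, sensitivity runs N = 500 with
B = 500 bootstrap replicates, and Monte-Carlo checks 20,000 chains; these
are the package's reference sizes and are configurable everywhere.
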