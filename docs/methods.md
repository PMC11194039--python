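# Methods

This note records the modeling assumptions, numerical choices and known
limitations behind `aoncb`. Symbols: pools are excitatory (e) and inhibitory
(i); K inputs per pool, individual rate r (Hz), dimensionless weight w,
pairwise spiking correlation ρ ∈ [0, 1); membrane time constant τ (s),
reversal potentials Ve > 0 > Vi (mV, leak at 0).

## Synchrony model

Inputs within a pool are exchangeable: the joint law of the binary activation
pattern in a time bin is invariant under relabeling. de Finetti's theorem then
represents the pattern as conditionally independent Bernoulli draws given a
random activation probability θ with directing measure F. We use beta
marginals, Beta(α, β), for which the per-bin coactivation count is
beta-binomial and ρ = 1/(1 + α + β). Holding the rate r fixed while the bin
size Δt → 0 forces α → 0, and the aggregate drive converges to a compound
Poisson process: events at rate b = r β (ψ(β+K) − ψ(β)), jump counts
p_k ∝ C(K,k) B(k, β+K−k) on 1..K, and ρ = 1/(1+β). The identity
ψ(β+K) − ψ(β) = Σ_{j<K} 1/(β+j) (K integer) is used everywhere; it is exact
and immune to the cancellation a naive digamma difference suffers at large β.
ρ = 0 is represented symbolically as β = ∞ (point mass on single
activations), never as a large float.

Excitation/inhibition coupling comes in the two closed-form cases: independent
pools (jumps are purely-e or purely-i, block masses be/(be+bi) and
bi/(be+bi), b = be + bi) and maximal coupling (θe = θi, common rate r,
joint pmf ∝ C(Ke,k) C(Ki,l) B(k+l, β+Ke+Ki−k−l) on the grid minus (0,0)).
Maximal coupling leaves the within-pool correlations at 1/(1+β) and produces
ρei = ρ, the upper bound √(ρe ρi); intermediate ρei would require a copula
construction with no closed form and is out of scope, as are negative or
time-lagged E/I correlations. The user-facing parameter is ρ (what experiments
report); β = 1/ρ − 1 is internal. Weight heterogeneity is supported as a
mixture of k-fold convolutions of a weight density over the jump counts.

## Voltage model and simulation

The AONCB neuron replaces exponentially decaying synaptic conductances with
all-or-none pulses: height C·w/τs for duration τs per activation, overlapping
pulses adding (no saturation). The 1/τs amplitude scaling preserves the charge
transfer per event, so the instantaneous-synapse limit ε = τs/τ → 0 keeps
finite voltage variability; in that limit the drive is shot noise and the
voltage obeys an exact event-driven scheme: closed-form exponential relaxation
toward I/G between events and the Marcus jump
J = ((We Ve + Wi Vi)/(We+Wi) − V)(1 − e^−(We+Wi)) at events. The jump targets
the conductance-weighted reversal potential, so the voltage can never leave
[Vi, Ve]; this is asserted on every simulated test trace.

Finite ε is integrated with an explicit Euler scheme (default
dt = min(τs/20, τ/200); coarser steps are rejected). Pulses are aligned to the
true event times with fractional-weight corrections at the partially covered
edge bins, which keeps the integrated conductance per pulse exactly W and
avoids an O(dt) rate bias. Closed-form finite-ε efficacies are not
implemented; finite-ε behavior is covered by simulation only, with tests
asserting monotone convergence of the moments to the event-driven values over
ε ∈ {0.25, 0.025, 0.0025} on a shared drive.

Trace moments are computed from the event-segment representation by exact
integration of each exponential segment (no sampling grid), after a default
burn-in of 20 τ. Standard errors use batch means over 50 equal time batches
(batch length ≫ the autocorrelation time τ_eff ≤ τ); segments are attributed
to the batch containing their start, a negligible edge effect for the batch
lengths used. Calibration over 40 independent runs shows the resulting
z-statistics are unbiased with unit variance. The sequential recursions (event
scan, Euler, OU) are numba-compiled; everything else is vectorized numpy.

The integrate-and-fire variant checks threshold crossings at jump times, which
is exact while I/G < VT because between events the voltage then decays toward
a subthreshold equilibrium; if I/G ≥ VT the continuous upward crossing between
events is solved in closed form. Exact stationary moments *with* reset are not
attempted. The diffusion comparison uses an Ornstein–Uhlenbeck surrogate with
relaxation time τ_eff = τ/(1 + ae,1 + ai,1) and noise chosen to match the
exact stationary mean and variance; the construction of the published
diffusion comparison is not fully specified in the source material, and this
moment-matched OU reading is our design choice.

## Moments and approximations

Efficacies are exact weighted sums over the jump pmf. The auxiliary
second-order efficacy ae,12 is computed from its squared-saturation form
(bτ/2) E[x (1 − e^−s)²], and ae,2 is then obtained from the identity
ae,2 = ae,1 − ae,12, so the identity holds to machine precision and the
difference suffers no cancellation. The variance formula's factorized origin
guarantees non-negativity; a negative value beyond rounding raises rather than
being clipped silently. The mean inside the variance formula is always the one
computed from the same efficacy set.

The small-weight approximation linearizes the saturation: mean from
ae,1 ≈ K r τ w (correlation-free), variance

    [ (1+ρe(Ke−1)) Ke re we² (Ve−E[V])² + (1+ρi(Ki−1)) Ki ri wi² (Vi−E[V])²
      − 2 ρei √(re ri) Ke we Ki wi (Ve−E[V])(E[V]−Vi) ]
    / (2 (1/τ + Ke re we + Ki ri wi)),

with the within-pool correction ≥ 0, the cross-pool correction ≤ 0, and the
decomposition asynchronous + Δwithin + Δcross exact by construction. A warning
fires when weights exceed 0.05. The linearization error metric is defined on
the *first-order* efficacy, |ae,1 − K r τ w|/ae,1 (r and τ cancel); defining
it on second-order efficacies would give materially larger errors, so the
choice matters and is deliberate.

The infinite-input scaling limit (we = Ωe/Ke, Ke → ∞, excitation only) drives
the neuron with the degenerate beta Lévy measure
ν(dw) = (re βe/w)(1 − w/Ωe)^{βe−1} dw on (0, Ωe). The three saturation
integrals ∫(1−e^−w) ν, ∫(1−e^−w)² ν, ∫(1−e^−2w) ν are finite (the integrands
vanish linearly at 0) and are evaluated with quadpack's algebraic-endpoint
weighted rule at relative tolerance 1e-10, the (1 − w/Ωe)^{βe−1} factor being
carried by the weight so only a smooth factor is sampled. ρe = 0 collapses the
measure onto zero-size jumps: zero variance, mean from the linear drive.

Bivariate jump grids are stored densely up to 2^24 entries (the largest grid
any workflow here needs is ≈ 2001×251); larger requests raise instead of
silently streaming.

## Drive sampling, jittering and empirical correlations

Drives are sampled by drawing a Poisson event count at rate b, uniform sorted
event times, and i.i.d. jump counts from the model pmf; all randomness flows
through a single numpy Generator per call, so fixed seeds reproduce
realizations bit for bit. Jittering splits an event of count k into k
unit-weight spikes, shifts each by an independent centered Gaussian of SD σJ,
and wraps times periodically into [0, T) to preserve stationarity and rate.

The empirical pairwise spike-count correlation uses the exchangeability
shortcut Var(S) = K v + K(K−1) c for the population count S, avoiding O(K²)
pair enumeration. For rasters, v is the mean per-input count variance from the
raster itself. For event-split spike trains, per-input marginals are
independently thinned Poisson processes of rate r (thinning of the Poisson
event process with i.i.d. retention marks k/K), a property preserved by
jittering, so v = r̂Δt with r̂ the observed per-input rate; this estimator is
flat in Δt and unbiased for unjittered synchronous drives. Jitter calibration
bisects the instantaneous correlation ρ∞ against a target binned correlation
using common random numbers per evaluation.

A caveat established while validating the jitter protocol: matching the
jittered drive and its instantaneous surrogate on the 25 ms spike-count
correlation leaves a small systematic variance mismatch. A small-weight kernel
calculation (pair displacements N(0, 2σJ²) weighted by the exponential
voltage kernel e^{−|u|/τ_eff}) puts the exact-match bin near 2 τ_eff ≈ 26 ms
for the standard parameters; at 25 ms the surrogate under-predicts the
jittered variance by ≈ 2%, and long simulations (3 × 2000 s per condition)
measure a total discrepancy of ≈ 3–5% once the calibration residual is
included. The package reports this comparison as computed.

## Synthetic data and scope

All inputs are generated by the package itself; defaults reflect the standard
study conditions: τ = 15 ms, Ve = 60 mV, Vi = −10 mV, large weights
we = 0.01/wi = 0.04 with Ke = 100/Ki = 25, moderate weights
we = 0.001/wi = 0.004 with Ke = 1000/Ki = 250, rates 0–50 Hz, correlations
0–0.03, aggregate weight Ke we = Ki wi = 1. Validation runs use T = 200 s per
condition and |z| ≤ 3 acceptance; sweeps default to 10 points per axis; the
jitter comparison uses 2000 s runs. The generator emulates stationary,
temporally uncorrelated synchrony with identical weights per pool; it does not
emulate rate nonstationarity, refractoriness, bursting, synaptic saturation,
negative or lagged E/I correlations, or postspiking reset effects on the
stationary moments — so passing tests certify the mathematics of this model
class, not those features of real data. Sweeps over (re, ri) grids with
ρei > 0 use exact maximal-coupling models on the re = ri diagonal and the
small-weight forms off the diagonal, since no closed-form joint jump model
exists for ρei > 0 with unequal rates.
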