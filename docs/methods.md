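# Methods

## The choice model

Hospital choice is modelled as a conditional (McFadden) logit. For
patient *i* and center *j* in the choice set `C_i` (all centers within
`max_minutes` of travel, default 180), the deterministic utility is

    V_ij = (β_t + γ_age z_age + γ_ses z_ses + γ_com z_com
            + γ_lon z_lon + γ_rur z_rur) · t_ij
           + δ_media w_media + δ_teach w_teach + δ_robot w_robot

with `t_ij` in minutes. There are no alternative-specific constants:
center heterogeneity enters only through the three attribute flags, and
patient characteristics — which do not vary across alternatives —
enter only as travel-time interactions. The base case (all z = 0) is a
man under 65, affluent, without comorbidity, living in an urban area
outside London; London and rural are dummies against "other urban".
Exponentiated coefficients are odds ratios: per minute of travel for
the `β/γ` terms, per attribute for the `δ` terms, and interaction ORs
multiply the base travel-time OR (e.g. an elderly, comorbid Londoner's
per-minute OR is the product of the four relevant ORs).

A consequence of the logit form that the whole pipeline leans on is
IIA: probabilities over any subset of a choice set equal the full-set
probabilities renormalized. Post-closure predictions are therefore the
same model evaluated on the surviving subset, with no refitting.

### Estimation

Maximum likelihood on the stacked patient × alternative design, with
analytic score and observed information, by Newton iteration with
step-halving. The log-likelihood is globally concave, so a zero start
is reliable. Convergence is declared when the score max-norm falls
below `tol` (default 1e-6) **or** the Newton decrement — the expected
gain of the next step — falls below the floating-point noise of the
log-likelihood (64 eps · (1 + |ll|)); at the ~5 × 10⁵-row designs used
here the likelihood is only representable to ~1e-11 relative, so a
fixed absolute gradient threshold alone would chase noise. The
line-search acceptance uses the same noise allowance. Covariance is the
inverse observed information at the optimum; intervals are Wald with
z = 1.96 and p-values are two-sided Wald tests (declared in the output
metadata). A coefficient escaping |β| > 1000 raises a separation
diagnostic rather than returning a spurious fit. `fit(..., terms=...)`
restricts estimation to an identified subset for degenerate designs
(e.g. toy problems where the attribute dummies sum to a within-set
constant, a direction the softmax cannot identify).

Choice probabilities are computed as max-subtracted softmaxes;
group-wise reductions use `np.*.reduceat` on contiguous patient blocks.

## Choice sets and exclusions

"Within 3 hours" is read inclusively: a center at exactly 180.0 minutes
is in the choice set, one rule everywhere. Alternatives are ordered by
minutes, ties by lowest center id (the same tie-break used for
nearest-center assignment). Cohort exclusions are applied in a fixed
order — first patients whose actually chosen center lies beyond the
threshold, then patients left with a single alternative — so a patient
qualifying for both is counted once, in the first bucket. The filter is
idempotent and the report counts partition the input exactly.

## Closure scenarios

* **A (volume)** closes centers with annual volume strictly below the
  threshold (default 50/year); a center at exactly 50 stays open.
* **B (facilities)** closes centers without radiotherapy on site,
  independent of volume.
* **C (capacity)** computes, per center, observed patient flow minus
  the flow expected if every patient attended their nearest center, and
  closes the net-loss centers; a zero net gain counts as a winner. The
  nearest-center baseline is a declared design choice; net gains sum to
  zero by construction, so at least one center always survives.

Affected patients are those whose chosen center closes; stranded
patients are affected patients whose choice set contains no surviving
center. Stranded patients get no preference-weighted prediction (the
model is only defined within the 3-hour choice set); they are counted
and summarized separately with the travel time to the nearest open
center regardless of distance.

## Travel burden

Per affected, non-stranded patient: pre-closure time is the time to the
*actually chosen* center (not the nearest); the preference-weighted
post-closure time is `Σ p_ij t_ij` over surviving in-range centers with
renormalized logit probabilities; the comparator is the nearest
surviving in-range time. Because a weighted mean cannot fall below the
minimum of its support, the comparator bounds the weighted prediction
from below patient by patient — the qualitative "distance minimization
understates burden" finding holds by construction and is asserted on
every run. Aggregate relative increases are ratios of means
(mean delta / mean pre), not means of ratios; this is declared in the
output metadata.

## Equity regression

OLS of the preference-weighted delta on the five patient dummies with
intercept, classical (homoskedastic) SEs, 95% CIs, two-sided p-values —
via statsmodels behind the module surface. Stranded patients are
dropped (they have no weighted delta). The intercept is the base-case
extra travel in minutes; coefficients are adjusted group differences.
A rank-deficient design (e.g. no rural patients affected) raises an
error naming the offending columns instead of returning unstable
estimates.

## The synthetic cohort

The generator emulates the *structure*, not the geography, of the
national cohort on an abstract 500 × 500 km plane:

| parameter | default | rationale |
| --- | --- | --- |
| n_patients / n_centers | 19,029 / 65 | national cohort dimensions |
| region weights | 0.14 / 0.63 / 0.23 | London / other-urban / rural shares |
| covariate prevalences | 0.42, 0.07, 0.48 | age ≥ 65, comorbidity, low SES |
| center attributes | 0.40, 0.35, 0.15, 0.63 | robotic, teaching, media, radiotherapy; the last reproduces ~24/65 non-comprehensive centers, the first three are plausibility choices |
| volume distribution | lognormal, median 58, σ = 0.9 | right-skewed; puts ~43% of centers under the 50/year threshold |
| speed | 60 km/h | km ≈ minutes |
| London congestion factor | 2.0 | dense-but-slow travel within the capital |

Patients are placed in Gaussian clusters by residence class (one London
cluster, 12 other-urban clusters, uniform rural scatter); centers are
placed preferentially in the same clusters with a 10% uniform "district
hospital" share. Travel time is straight-line distance at constant
speed, doubled when both endpoints lie within 40 km of the London
centroid — membership is geometric so it is computable from the
coordinate columns alone. Covariates are drawn independently; real
characteristics are correlated (rural residence and deprivation, for
instance), so equity estimates on synthetic data test the machinery,
not the sociology. Chosen centers are sampled by the Gumbel-max
construction, which draws exactly from the conditional-logit
probabilities; the published national odds ratios are the default
data-generating truth, making refitting a direct parameter-recovery
check. Every stochastic operation takes an explicit integer seed and
identical configuration + seed reproduces every table bit for bit.

With these defaults a full-size synthetic run has a mean pre-closure
travel time of ~31–32 minutes and ~25 alternatives per choice set,
matching the scale of the national data; unlike the registry cohort it
produces no far-traveller exclusions (choices are drawn within the
3-hour set by construction) and its stranded share under scenario C
runs a few percent rather than 3%.

## What the recovery experiments show

Because the registry data are restricted, correctness is demonstrated
by simulation: generate choices from known coefficients, refit, and
check the truth falls inside the fitted 95% CI. The acceptance script
does this at n = 20,000 patients / 60 centers for the choice model and
n = 4,000 for the equity OLS; the test suite additionally verifies
~95% empirical CI coverage over 100 replicates at n = 2,000 (accepting
88–99%). A single CI check has a ~5% per-term false-alarm rate by
design; the coverage replicates are the calibrated version of the same
claim. Passing these shows the estimator and its uncertainty are
correct for data generated by the model — not that the model is a
correct description of real hospital choice (IIA, linearity in
minutes, and independent covariates are all assumptions).

## Problem sizes and numerical choices in the tests

Unit and property tests run on a 1,500-patient / 20-center synthetic
study plus hand-enumerable toys; the coverage studies use 100 × 2,000
patients / 50 centers (50 centers keeps every attribute represented, so
the information matrix stays nonsingular across replicates). Softmax
normalization is asserted to 1e-10, IIA renormalization to 1e-10,
analytic score against central finite differences to 1e-6 relative, and
OLS residual orthogonality to 1e-8.

## Known limitations

Straight-line constant-speed travel (no road network, no public
transport); no correlation among patient covariates; no capacity
constraints at surviving centers; no alternative-specific constants or
nested/mixed logit relaxations of IIA; closure rules are applied once,
with no dynamic re-equilibration of volumes after closures.
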