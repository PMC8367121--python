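# Methods

## Setting

A clinical NLP system labels each EHR document as mentioning or not
mentioning each clinical variable of interest. Evaluation is at the
document level, per variable: the system's binary labels are compared to
an adjudicated gold standard, and precision, recall and F1 are reported
with confidence intervals. One *primary* variable (the condition the
study is about) gets a statistically sized sample; *secondary* variables
are represented in the same sample without size guarantees.

## Exact intervals

All proportions carry Clopper–Pearson intervals: with r successes in n
trials and significance level α,

    lower = BetaInv(α/2;     r,     n − r + 1)        (0 when r = 0)
    upper = BetaInv(1 − α/2; r + 1, n − r)            (1 when r = n)

The equivalent F-distribution form is kept as a verification path and
the two are tested to agree to 1e-9. Degenerate ends (r = 0, r = n) are
returned in closed form rather than through a quantile call with a zero
shape parameter. Clopper–Pearson is conservative: exact-enumeration
coverage is at least the nominal level, which the tests check by
enumeration at n = 40, p = 0.8.

## Sample sizing

Inputs: confidence level 1 − α, CI half-width h (the interval should
span roughly ±h around the estimate), expected precision P, expected
recall R, and the event frequency f — the proportion of documents in the
target population flagged for the primary variable. f can be supplied
directly ("external") or computed ("internal") as the **unweighted mean
over hospitals** of per-hospital ratios (documents mentioning the
variable / documents in scope), so every site contributes equally.

Let N(p) be the smallest n whose Clopper–Pearson interval at the
expected proportion p (success count rounded half-up) is no wider than
2h. N(·) is found by a linear scan from n = 1, evaluated in vectorized
blocks, with a hard cap (default 10^6) that raises an explicit error
when exceeded — low-frequency variables can demand infeasibly many
documents, and that situation should surface loudly. Write
N_P = N(expected precision) and N_R = N(expected recall).

The gold standard is assembled from documents the system's
pre-annotation flags as positive and from unflagged documents:

    n_positive = max( round(N_R · R / P), N_P )
    n_total    = round( N_P / (P · f) )
    n_negative = max( n_total − n_positive, 0 )

Reading of the three lines:

* Recall's denominator is the set of truly positive documents, of which
  a share R is detected. The detected share must come from the flagged
  stratum, whose expected truly-positive yield is P per document, so the
  flagged stratum needs about N_R·R/P documents; it must in any case
  reach N_P, the denominator the precision interval needs.
* A randomly drawn document is a correctly flagged positive with
  probability P·f, so a corpus of N_P/(P·f) documents is needed for the
  flagged-and-correct core of the evaluation; the remainder after the
  positive stratum is drawn as negatives, which supply the
  missed-positive (FN) share of the recall denominator and anchor the
  sample's composition to the corpus frequency.

The combination rule was calibrated so that the package reproduces the
published multi-hospital asthma worked example exactly — (confidence
0.95, h = 0.05, P = 0.85, R = 0.80, f = 0.485) yields 249 positives,
270 negatives, 519 documents — and so that the calculator behaves
qualitatively correctly around it: rarer events require more negatives
(n_total scales like 1/f), tighter widths require more documents
(N(p) ≈ 4z²p(1−p)/(2h)² grows quadratically as h shrinks), and more
optimistic P/R expectations never increase the total. These three
monotonicities are asserted by the test suite over a grid of expected
values in [0.6, 0.95], varied one at a time from the worked example.
The split is deliberately conservative in the allocation step too: each
of k hospitals receives ceil(n_positive/k) positives and
ceil(n_negative/k) negatives, so summed allocations may slightly exceed
the totals (six hospitals get 42 + 45 = 87 documents each in the
example, i.e. 252 positives and 270 negatives in aggregate).

Two caveats are documented rather than hidden. First, n_positive is
sized so the *expected* detected yield covers the recall denominator's
detected share; the recall interval's width is then guaranteed in
expectation, not per realization. Second, in extreme corners (high f
combined with R far below P) the negative stratum can clamp to zero;
the calculator keeps totals non-increasing in the expectations but such
corners are outside the regime the method is intended for (realistic
expectations around 80%, frequencies well below saturation).

"CI width 5%" is interpreted as half-width ±5% (total width 10%)
throughout: sizing a recall of 0.8 to a *total* width of 5% would need
roughly a thousand positive documents, which is inconsistent with the
scale of gold standards this methodology is designed to produce.

## Document selection

Selection is seeded and deterministic: one integer seed drives a single
generator; hospitals are processed in sorted order; within each
hospital, the primary positives (flag true) and negatives (flag false)
are drawn uniformly without replacement. A hospital that cannot fill a
quota raises an "insufficient stratum" error naming the hospital, the
stratum and the available vs required counts.

Secondary variables are a representation goal, not a sized estimate:
positives already inside the selection count toward each variable's
quota (default 20, configurable) and only the shortfall triggers new
draws from that variable's positive stratum; secondary negatives
(default quota 0) are drawn exclusively from documents whose primary
flag is false, mirroring how secondary negatives must not silently
re-introduce primary positives. Exhausted secondary strata produce
warnings recorded in the selection, never errors. A document may serve
simultaneously as, say, primary-negative and secondary-positive; the
stratum label records the reason for inclusion, while analysis always
goes back to the flags.

## Annotation and adjudication

Two annotators label every selected document for every variable,
blindly and independently. Cells where they agree enter the gold
standard as consensus; the curator decides every disagreement cell, and
only those — curator labels on agreement cells are ignored with a
warning, and a missing curator label on a disagreement is an error
naming the cell. The result is symmetric in the annotator order.
Annotation files use an explicit grid by default: a missing
(document, variable) cell is a validation error, because treating
absence-of-a-row as an absent label is the classic silent corpus bug.

IAA is pairwise F1 (one annotator as reference; swapping annotators
exchanges precision and recall and leaves F1 unchanged). Cohen's kappa
is deliberately not offered.

## Metrics and intervals

Precision and recall get Clopper–Pearson intervals on their natural
denominators (TP + FP and TP + FN). F1 has no exact binomial interval;
its interval is constructed as the harmonic mean of the precision and
recall bounds (lower from the lowers, upper from the uppers), keeping
the three intervals mutually consistent and the F1 interval inside
[min, max] of the component intervals. Zero denominators report the
metric as 0.0 with a `defined = False` flag, never an exception; F1 is
0 when either component is 0. Display rounding is half-up to 2
decimals; JSON reports keep full precision and round-trip losslessly.

## Synthetic corpora

The generator emulates the statistical skeleton of a multi-hospital
study: truth labels are independent coin flips per document and
variable at configured prevalences (per-hospital rates for the primary
variable); annotator labels are truth flipped at per-annotator false
present/false-absent rates; system predictions follow per-variable
sensitivity/specificity; the curator is oracle truth by default
(configurable error rate), so gold-standard error is controllable and
parameter recovery is exact in the limit. Defaults mirror a realistic
six-hospital study: primary prevalence 0.485, secondary prevalences
0.05–0.35, annotator flip rates 0.08 (placing pairwise-F1 agreement in
the 0.75–0.90 band typical of document-level tasks), system sensitivity
0.96 / specificity 0.94.

What it does not model: correlated variables (each is independent; an
optional nesting of a child variable under a parent was considered and
deferred), document difficulty (noise is i.i.d. label flipping),
hospital-specific language or any text at all. Passing tests on
synthetic data therefore demonstrate the statistical machinery —
sizing, sampling, adjudication, interval coverage — not the linguistic
performance of any system.

Test and simulation sizes were chosen to keep the full suite fast while
leaving the statistical assertions well-powered: coverage checks use
200 seeded replicates of a 400-document corpus (about 194 expected
positives each, comfortably enough for the recall interval to be
non-degenerate), and convergence checks compare 1 000 against 16 000
documents averaged over five seeds.

## Numerical conventions

* Success counts at expected proportions: nearest integer, .5 rounds up.
* Sample-size search: linear scan from n = 1 (the minimum is taken over
  a criterion that is not monotone in n at fixed rounding, so scanning
  is the definition, not an approximation); cap 10^6.
* Seeds: a single integer seed per randomized operation;
  sub-streams are derived with `SeedSequence` spawn keys so adding
  secondary draws never perturbs the primary selection.
* Display rounding: decimal half-up, two places.
* All randomness goes through `numpy.random.Generator`; nothing reads
  global RNG state.
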