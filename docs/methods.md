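# Methods

## Data model

A study is a `ResponseSet`: individuals (id, classroom, gender, ten AUDIT
item scores, other instrument totals as opaque numbers) plus at most one
directed roster rating per ordered pair, weight 1–5. Ratings are confined
to a classroom unless the study explicitly allows cross-classroom ties.
Gender is binary (`male`/`female`); the published cut-off literature this
package operationalizes is stated only for those two categories, so
gender-scoped rules must be extended explicitly before other values can be
admitted.

AUDIT items 1–8 take scores 0–4; items 9–10 are three-option items scored
0/2/4, and odd values there are validation errors, not data. The AUDIT
total is the plain sum (0–40); AUDIT-C is the sum of items 1–3 (0–12).
Items are stored pre-scored; a text-option mapping covers field data that
arrives as printed response texts.

**Missing roster answers.** A roster question asks about *every* classmate,
so an unanswered pair is most plausibly the floor response rather than
missing data. The default policy scores an unanswered within-classroom
direction as weight 1 ("never spend time together") and logs how many
directions were filled; a `strict` mode leaves the direction absent, which
fails reciprocity and excludes the dyad from sum/mean conditions. The
choice is a configurable guess — real studies should check which reading
matches their administration protocol.

## Tie rules

A tie rule is a conjunction over a dyad's two directed weights:
reciprocity (both directions present), per-direction minimum, minimum sum
(2–10), minimum mean (1–5). Conditions on weights are evaluated over the
present directions; disjunctive sum/mean semantics are deliberately not
offered — every condition written is required. Derived networks are
undirected (reciprocity plus dichotomization make ties symmetric) with the
full node set retained, so scenario comparisons always work over the same
nodes. `output_weighting` (`dichotomous` default, `min`/`mean`/`sum`)
keeps a weighted variant available.

Thresholds are integers against integer weights, so the strict/non-strict
phrasings in the literature ("weights of > 3" vs "weight 4 or 5") coincide;
rules are written with explicit comparators rather than normalized, and a
dedicated test family asserts `gt k` ≡ `ge k+1` across the full score
ranges.

## Characteristic rules

OR-of-ANDs over score conditions; richer boolean nesting is rejected at
parse time because every published definition in scope fits this form and
flat clauses keep explanation traces readable. A clause applies to an
individual only if every condition's gender scope matches; scope never
flips a truth value. Metric conditions (`sna_metric:<name>`) resolve
against the metric table of the scenario's own derived network — by design
the same label name can differ across scenarios, which is the point of the
sensitivity analysis. On an undirected derived network `in_degree` and
`out_degree` are reported equal to the undirected degree, so "named by
four or more peers" reads as degree on the derived friendship network.

The binge-drinker presets read AUDIT-C, the consumption subscore the
source cut-off studies were calibrated on: Finnish `gt 7` males / `gt 4`
females (with a `ge 7` male variant, since the source is quoted as "7 or
8"), Spanish `gt 4` any gender (with a `ge 4` variant, since "best cut-off
point 4" is ambiguous about inclusivity).

## Explanations

Every tie and label verdict carries an `Explanation`: per-condition
records (description, observed value, threshold, satisfied flag, clause
index) plus the boolean structure. `replay()` recomputes the verdict from
the records alone, and the test suite asserts replay equals the original
verdict everywhere — the trace is sufficient evidence, not a log.

## Metrics

Standard unweighted measures via networkx: in/out/undirected degree,
normalized betweenness, closeness with the reachable-fraction scaling
(an isolate's closeness is 0 by convention), connected components (weak
components on the raw directed network), density, and the raw-arc
reciprocity rate (fraction of arcs whose reverse exists; defined as 1 on
an arcless network). Brute-force BFS implementations of betweenness (pair
dependency σ(s,v)·σ(v,t)/σ(s,t)) and closeness live in the test suite as
independent oracles.

## Scenario comparisons

Edge similarity is the Jaccard index over unordered edge sets, defined as
1 when both sets are empty. Label agreement per shared label name: 2×2
confusion counts, observed agreement, and Cohen's κ. A degenerate marginal
(expected agreement 1, e.g. both scenarios label everyone or no one) makes
κ 0/0; it is reported as 1.0 with a `kappa_degenerate` flag, preserving
the agreement signal without inventing disagreement. All C(k,2) pairs are
compared by default; a reference-scenario mode curbs the quadratic output.
No significance testing (QAP and friends) is attempted — the statistics
are descriptive.

## Synthetic study generator

The generator emulates the *shape* of a multi-classroom adolescent roster
study, not any real study's marginals. Defaults: 9 classrooms of 23–25
students (≈ 214 total), 50% female, 4 planted friendship groups per
classroom. Within-group dyads draw ratings from a high-weight distribution
(mass 0.70 on weights 4–5), between-group dyads from a low-weight one
(mass 0.85 on weights 1–2); the second direction of a dyad copies the
first except with probability 0.25 (`rating_reciprocity_noise`), when it
is redrawn independently. Every ordered within-classroom dyad is rated
exactly once.

Drinking propensity θ ∈ [0,1] mixes a per-group draw g and a per-individual
draw u as θ = h·g + (1−h)·u with h = `drinking_homophily` (default 0.6).
Each AUDIT item is drawn from (1 − s·θ)·base + s·θ·heavy, where `base` and
`heavy` are the low/high-consumption response distributions and the item
strength s is 1.0 for items 1–3, 0.4 for items 4–8, 0.3 for items 9–10 —
the propensity acts most strongly where the AUDIT-C classifiers look, so
the homophily knob visibly moves same-label clustering on derived
networks. All draws flow from one `numpy` generator seeded by the config,
making studies byte-identical on disk per seed.

What this does **not** emulate: real marginal distributions of AUDIT
responses, degree heterogeneity beyond the planted partition, gender
homophily in tie formation, longitudinal waves. Passing tests demonstrate
the machinery's correctness and the qualitative phenomena (nesting,
containment, homophily recovery), not quantitative agreement with any real
population.

## Anonymization

Pseudonyms are HMAC-SHA256(secret, id) prefixes, lengthened until
injective; the same secret reproduces the same pseudonyms, and networks
and metrics are invariant under the renaming (asserted by test). The
pseudonym map is only written out on explicit request.

## Numerical and design conventions

- Mean-weight conditions compare exact rationals (`Fraction`), so 3.5
  thresholds behave exactly on half-integer means.
- Scenario enumeration order is tie-rule major in declaration order;
  labels are `"<tie>|<characteristic names>"` and must be unique.
- Networks are per-classroom constructions; the default whole-study graph
  is their disjoint union (cross-classroom dyads are only evaluated when
  cross-classroom ratings exist), so study-level reports and per-classroom
  analyses agree edge-for-edge.
- Component ids are ordered by component size, ties broken by smallest
  node id; they are labels, not quantities.
- Problem sizes in the test suite (random networks n ≤ 30, 50-seed
  property sweeps, 2-classroom homophily contrasts) were chosen to make
  the property distributions stable while keeping the default suite fast.

## Known limitations

- No OWL/RDF serialization or description-logic reasoning: the rule
  registry plus explanation traces provide the needed fidelity here.
- Clause structure is fixed at OR-of-ANDs; arbitrary boolean nesting and
  disjunctive sum/mean tie conditions are rejected rather than silently
  reinterpreted.
- Item-level scoring is implemented only for the AUDIT; other instruments
  enter as precomputed totals.
- No longitudinal or dynamic network analysis; one wave per study.
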