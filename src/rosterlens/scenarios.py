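"""The what-if engine: run every tie rule x characteristic rule combination.

Combining n tie definitions with m characteristic definition sets yields
n x m analyses of the same questionnaire data. Each scenario derives its
network, computes metrics on it, classifies every individual (metric-backed
rules such as "popular" read the scenario's own network), and the results
are then compared pairwise: edge-set Jaccard, per-label confusion counts,
observed agreement and Cohen's kappa, and per-node metric deltas.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .definitions import CharacteristicRule, Explanation, TieRule, classify_individual
from .errors import ValidationError
from .network import (
    MetricTable,
    build_raw_network,
    compute_metrics,
    derive_network,
    write_graphml,
)
from .questionnaire import ResponseSet


@dataclass(frozen=True)
class Scenario:
    """One tie rule paired with the characteristic rules to evaluate on it."""

    tie_rule: TieRule
    characteristic_rules: tuple[CharacteristicRule, ...]
    label: str


def enumerate_scenarios(
    tie_rules: Sequence[TieRule],
    characteristic_rule_sets: Sequence[Sequence[CharacteristicRule]],
) -> list[Scenario]:
    """The full n x m cross-product, tie-rule major, in declaration order.

    Each characteristic-rule *set* is one alternative definition bundle (e.g.
    one binge-drinker definition together with its metric-based companions),
    so n tie rules x m bundles gives n x m scenarios, labelled
    ``"<tie>|<bundle names>"``.
    """
    if not tie_rules or not characteristic_rule_sets:
        raise ValidationError("need at least one tie rule and one characteristic rule set")
    names = [r.name for r in tie_rules]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate tie rule names in {names}")
    scenarios = []
    seen = set()
    for tie in tie_rules:
        for rule_set in characteristic_rule_sets:
            rule_set = tuple(rule_set)
            label = f"{tie.name}|{'+'.join(r.name for r in rule_set)}"
            if label in seen:
                raise ValidationError(f"duplicate scenario label {label!r}")
            seen.add(label)
            scenarios.append(Scenario(tie, rule_set, label))
    return scenarios


@dataclass
class ScenarioResult:
    """Everything one scenario produced, re-derivable from inputs + rules."""

    scenario: Scenario
    network: nx.Graph
    metrics: MetricTable
    labels: pd.DataFrame  # bool, index: individual id, columns: rule names
    explanations: dict[tuple[str, str], Explanation]  # (rule name, individual id)

    @property
    def label(self) -> str:
        return self.scenario.label

    def summary(self) -> dict:
        """Counts a reader wants first: edges, components, labels by gender."""
        genders = pd.Series(
            {n: d["gender"] for n, d in self.network.nodes(data=True)}, name="gender"
        )
        by_gender = {}
        for rule_name in self.labels.columns:
            labelled = self.labels[rule_name]
            by_gender[rule_name] = {
                "total": int(labelled.sum()),
                **{
                    g: int((labelled & (genders == g)).sum())
                    for g in ("male", "female")
                },
            }
        return {
            "scenario": self.label,
            "tie_rule": self.scenario.tie_rule.name,
            "n_nodes": self.metrics.graph["n_nodes"],
            "n_edges": self.metrics.graph["n_edges"],
            "density": self.metrics.graph["density"],
            "n_components": self.metrics.graph["n_components"],
            "label_counts": by_gender,
        }


def run_scenario(
    responses: ResponseSet,
    scenario: Scenario,
    classroom: str | None = None,
    missing_policy: str = "floor",
) -> ScenarioResult:
    """Derive the network, compute its metrics, then classify every individual.

    Metrics are computed before classification so that metric-conditioned
    rules resolve against this scenario's derived network. Deterministic:
    identical inputs and rules give identical results.
    """
    raw = build_raw_network(responses, classroom=classroom)
    net = derive_network(raw, scenario.tie_rule, missing_policy=missing_policy)
    metrics = compute_metrics(net)

    label_rows: dict[str, dict[str, bool]] = {}
    explanations: dict[tuple[str, str], Explanation] = {}
    for node in sorted(net.nodes):
        individual = responses.individuals[node]
        node_metrics = metrics.node_metrics(node)
        label_rows[node] = {}
        for rule in scenario.characteristic_rules:
            verdict, expl = classify_individual(rule, individual, node_metrics)
            label_rows[node][rule.name] = verdict
            explanations[(rule.name, node)] = expl
    labels = pd.DataFrame.from_dict(label_rows, orient="index").sort_index()
    labels.index.name = "id"
    return ScenarioResult(scenario, net, metrics, labels, explanations)


@dataclass
class LabelAgreement:
    """Agreement between two scenarios on one shared label."""

    label_name: str
    both: int
    only_a: int
    only_b: int
    neither: int
    agreement: float
    kappa: float
    kappa_degenerate: bool = False

    @property
    def n(self) -> int:
        return self.both + self.only_a + self.only_b + self.neither


def cohens_kappa(both: int, only_a: int, only_b: int, neither: int) -> tuple[float, bool]:
    """Cohen's kappa from a 2x2 confusion table.

    A degenerate marginal (expected agreement 1, e.g. both scenarios label
    everyone or no-one) is reported as kappa 1.0 with a degenerate flag —
    the observed agreement is then also 1, and 0/0 carries no disagreement
    signal.
    """
    n = both + only_a + only_b + neither
    if n == 0:
        return 1.0, True
    po = (both + neither) / n
    p_yes_a = (both + only_a) / n
    p_yes_b = (both + only_b) / n
    pe = p_yes_a * p_yes_b + (1 - p_yes_a) * (1 - p_yes_b)
    if pe == 1.0:
        return 1.0, True
    return (po - pe) / (1 - pe), False


@dataclass
class ComparisonReport:
    """How two scenarios differ: edges, labels, metrics."""

    label_a: str
    label_b: str
    edge_jaccard: float
    edges_both: int
    edges_only_a: int
    edges_only_b: int
    label_agreements: dict[str, LabelAgreement]
    metric_deltas: pd.DataFrame  # b minus a, per node, numeric metric columns

    def to_dict(self) -> dict:
        return {
            "scenario_a": self.label_a,
            "scenario_b": self.label_b,
            "edge_jaccard": self.edge_jaccard,
            "edges_both": self.edges_both,
            "edges_only_a": self.edges_only_a,
            "edges_only_b": self.edges_only_b,
            "labels": {
                name: {
                    "both": ag.both,
                    "only_a": ag.only_a,
                    "only_b": ag.only_b,
                    "neither": ag.neither,
                    "agreement": ag.agreement,
                    "kappa": ag.kappa,
                    "kappa_degenerate": ag.kappa_degenerate,
                }
                for name, ag in self.label_agreements.items()
            },
            "mean_abs_degree_delta": float(self.metric_deltas["degree"].abs().mean())
            if len(self.metric_deltas)
            else 0.0,
        }


def _edge_set(net: nx.Graph) -> set[frozenset]:
    return {frozenset(e) for e in net.edges}


def compare_scenarios(a: ScenarioResult, b: ScenarioResult) -> ComparisonReport:
    """Pairwise comparison of two scenario results over the same node set."""
    if set(a.network.nodes) != set(b.network.nodes):
        raise ValidationError(
            f"scenarios {a.label!r} and {b.label!r} cover different node sets"
        )
    ea, eb = _edge_set(a.network), _edge_set(b.network)
    union = ea | eb
    jaccard = 1.0 if not union else len(ea & eb) / len(union)

    agreements: dict[str, LabelAgreement] = {}
    for name in [c for c in a.labels.columns if c in b.labels.columns]:
        la = a.labels[name]
        lb = b.labels[name].reindex(la.index)
        both = int((la & lb).sum())
        only_a = int((la & ~lb).sum())
        only_b = int((~la & lb).sum())
        neither = int((~la & ~lb).sum())
        agreement = (both + neither) / len(la) if len(la) else 1.0
        kappa, degenerate = cohens_kappa(both, only_a, only_b, neither)
        agreements[name] = LabelAgreement(
            name, both, only_a, only_b, neither, agreement, kappa, degenerate
        )

    numeric = ["in_degree", "out_degree", "degree", "betweenness", "closeness"]
    deltas = b.metrics.nodes[numeric] - a.metrics.nodes[numeric]
    return ComparisonReport(
        label_a=a.label,
        label_b=b.label,
        edge_jaccard=jaccard,
        edges_both=len(ea & eb),
        edges_only_a=len(ea - eb),
        edges_only_b=len(eb - ea),
        label_agreements=agreements,
        metric_deltas=deltas,
    )


def sensitivity_report(
    results: Sequence[ScenarioResult],
    reference: str | None = None,
) -> dict:
    """Per-scenario summaries plus pairwise comparisons, as one JSON-able dict.

    All C(k, 2) pairs are compared by default; ``reference`` restricts to
    pairs involving one named scenario to curb quadratic output.
    """
    if not results:
        raise ValidationError("sensitivity_report needs at least one scenario result")
    pairs: Iterable[tuple[ScenarioResult, ScenarioResult]]
    if reference is None:
        pairs = itertools.combinations(results, 2)
    else:
        ref = next((r for r in results if r.label == reference), None)
        if ref is None:
            raise ValidationError(f"reference scenario {reference!r} not found")
        pairs = ((ref, r) for r in results if r.label != reference)
    return {
        "n_scenarios": len(results),
        "scenarios": [r.summary() for r in results],
        "comparisons": [compare_scenarios(a, b).to_dict() for a, b in pairs],
    }


def render_summary_table(report: Mapping) -> str:
    """Human-readable per-scenario summary table."""
    header = f"{'scenario':<42} {'edges':>6} {'comps':>6} {'density':>8}  labels"
    lines = [header, "-" * len(header)]
    for s in report["scenarios"]:
        labels = ", ".join(
            f"{name}={counts['total']} (M{counts['male']}/F{counts['female']})"
            for name, counts in s["label_counts"].items()
        )
        lines.append(
            f"{s['scenario']:<42} {s['n_edges']:>6} {s['n_components']:>6} "
            f"{s['density']:>8.3f}  {labels}"
        )
    return "\n".join(lines)


def write_report(
    results: Sequence[ScenarioResult],
    out_dir: str | Path,
    reference: str | None = None,
    provenance: Mapping | None = None,
) -> dict:
    """Write per-scenario exports plus the machine- and human-readable reports.

    Produces, under ``out_dir``: one GraphML + metrics CSV + labels CSV per
    scenario (file names embed the scenario label), ``report.json`` and
    ``summary.txt``. Returns the report dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for res in results:
        stem = res.label.replace("|", "__").replace("/", "_")
        write_graphml(_with_labels(res), out_dir / f"{stem}.graphml")
        res.metrics.to_csv(out_dir / f"{stem}.metrics.csv")
        res.labels.astype(int).to_csv(out_dir / f"{stem}.labels.csv")
    report = sensitivity_report(results, reference=reference)
    if provenance:
        report["provenance"] = dict(provenance)
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out_dir / "summary.txt").write_text(render_summary_table(report) + "\n")
    return report


def _with_labels(res: ScenarioResult) -> nx.Graph:
    g = res.network.copy()
    for rule_name in res.labels.columns:
        for node, val in res.labels[rule_name].items():
            g.nodes[node][rule_name] = bool(val)
    return g
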