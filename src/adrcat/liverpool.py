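"""The Liverpool ADR causality assessment tool as a data-driven decision tree.

Unlike the weighted Naranjo questionnaire, the Liverpool instrument is a
flowchart: each prompt has dichotomous (occasionally ternary) responses,
and routing leads either to a further prompt or to a terminal causality
category. The tree is loaded from a JSON document so prototype variants
and local adaptations can be evaluated with the same engine; the
packaged default encodes the final published instrument.

Structural validation goes beyond well-formedness: the development of
the instrument showed that early prototypes allowed paths to `Definite`
without a positive re-challenge or a previous reaction to the same drug,
inflating that category. The validator therefore checks a "Definite
gate": every root-to-Definite path must pass through a node tagged
``rechallenge_gate`` via that node's affirmative answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator, Mapping, Sequence

from .categories import CausalityCategory, parse_category

GATE_TAG = "rechallenge_gate"


class TreeValidationError(ValueError):
    """A tree document violates a structural invariant; lists all violations."""

    def __init__(self, violations: Sequence[str]):
        self.violations = list(violations)
        super().__init__("invalid decision tree:\n- " + "\n- ".join(self.violations))


class AssessmentError(ValueError):
    """An answer sheet cannot drive a traversal of the tree."""


@dataclass(frozen=True)
class Route:
    """Target of one answer: exactly one of node id / leaf id."""

    node: str | None = None
    leaf: str | None = None


@dataclass(frozen=True)
class DecisionNode:
    id: str
    prompt: str
    routes: Mapping[str, Route]
    tags: Mapping[str, str] = field(default_factory=dict)

    @property
    def allowed_answers(self) -> tuple[str, ...]:
        return tuple(self.routes)


@dataclass(frozen=True)
class DecisionLeaf:
    id: str
    category: CausalityCategory


@dataclass(frozen=True)
class LiverpoolAssessment:
    """Outcome of one traversal: final category plus the visited path."""

    category: CausalityCategory
    path: tuple[tuple[str, str], ...]  # (node id, answer) in visit order


@dataclass(frozen=True)
class CheckResult:
    name: str
    passed: bool
    details: tuple[str, ...] = ()


@dataclass(frozen=True)
class TreeDiagnostics:
    """Pass/fail report of the structural validation battery."""

    checks: tuple[CheckResult, ...]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def check(self, name: str) -> CheckResult:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class DecisionTree:
    nodes: Mapping[str, DecisionNode]
    leaves: Mapping[str, DecisionLeaf]
    root: str
    metadata: Mapping[str, object] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return str(self.metadata.get("name", "decision-tree"))


def _parse_route(raw: Mapping, node_id: str, answer: str, errors: list[str]) -> Route:
    keys = set(raw)
    if keys == {"node"}:
        return Route(node=str(raw["node"]))
    if keys == {"leaf"}:
        return Route(leaf=str(raw["leaf"]))
    errors.append(
        f"node {node_id!r}, answer {answer!r}: route must have exactly one of "
        f"'node' or 'leaf', got {sorted(keys)}"
    )
    return Route()


def load_tree(document) -> DecisionTree:
    """Build a :class:`DecisionTree` from a JSON document, path, or dict.

    The document must pass the structural half of validation (unique ids,
    existing route targets, acyclicity, parseable leaf categories);
    otherwise a :class:`TreeValidationError` listing every violation is
    raised. Semantic diagnostics (category coverage, Definite gate) are
    reported by :func:`validate_tree` and do not block loading.
    """
    if isinstance(document, Mapping):
        doc = document
    else:
        with open(document, encoding="utf-8") as fh:
            doc = json.load(fh)

    errors: list[str] = []
    nodes: dict[str, DecisionNode] = {}
    leaves: dict[str, DecisionLeaf] = {}

    for raw in doc.get("nodes", []):
        nid = str(raw["id"])
        if nid in nodes:
            errors.append(f"duplicate node id {nid!r}")
            continue
        routes = {
            str(ans): _parse_route(tgt, nid, str(ans), errors)
            for ans, tgt in raw.get("routes", {}).items()
        }
        if len(routes) < 2:
            errors.append(f"node {nid!r} has fewer than two answer routes")
        nodes[nid] = DecisionNode(
            id=nid,
            prompt=str(raw.get("prompt", "")),
            routes=routes,
            tags={str(k): str(v) for k, v in raw.get("tags", {}).items()},
        )

    for raw in doc.get("leaves", []):
        lid = str(raw["id"])
        if lid in leaves or lid in nodes:
            errors.append(f"duplicate id {lid!r}")
            continue
        try:
            leaves[lid] = DecisionLeaf(id=lid, category=parse_category(raw["category"]))
        except (KeyError, ValueError) as exc:
            errors.append(f"leaf {lid!r}: {exc}")

    root = str(doc.get("root", ""))
    if root not in nodes:
        errors.append(f"root {root!r} is not a node id")

    for node in nodes.values():
        for ans, route in node.routes.items():
            if route.node is not None and route.node not in nodes:
                errors.append(
                    f"node {node.id!r}, answer {ans!r}: dangling node target "
                    f"{route.node!r}"
                )
            if route.leaf is not None and route.leaf not in leaves:
                errors.append(
                    f"node {node.id!r}, answer {ans!r}: dangling leaf target "
                    f"{route.leaf!r}"
                )

    tree = DecisionTree(
        nodes=nodes, leaves=leaves, root=root, metadata=doc.get("metadata", {})
    )
    if not errors:
        errors.extend(_cycle_violations(tree))
        unreachable = _unreachable(tree)
        if unreachable:
            errors.append(f"unreachable from root: {sorted(unreachable)}")
    if errors:
        raise TreeValidationError(errors)
    return tree


def _cycle_violations(tree: DecisionTree) -> list[str]:
    # Iterative colour DFS over node->node edges.
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {nid: WHITE for nid in tree.nodes}
    out: list[str] = []
    for start in tree.nodes:
        if colour[start] != WHITE:
            continue
        stack: list[tuple[str, Iterator[str]]] = [
            (start, iter(_node_children(tree, start)))
        ]
        colour[start] = GREY
        while stack:
            nid, children = stack[-1]
            child = next(children, None)
            if child is None:
                colour[nid] = BLACK
                stack.pop()
            elif colour[child] == GREY:
                out.append(f"cycle through node {child!r}")
            elif colour[child] == WHITE:
                colour[child] = GREY
                stack.append((child, iter(_node_children(tree, child))))
    return out


def _node_children(tree: DecisionTree, nid: str) -> list[str]:
    return [
        r.node
        for r in tree.nodes[nid].routes.values()
        if r.node is not None and r.node in tree.nodes
    ]


def _unreachable(tree: DecisionTree) -> set[str]:
    seen: set[str] = set()
    frontier = [tree.root] if tree.root in tree.nodes else []
    while frontier:
        nid = frontier.pop()
        if nid in seen:
            continue
        seen.add(nid)
        for route in tree.nodes[nid].routes.values():
            if route.node is not None:
                frontier.append(route.node)
            elif route.leaf is not None:
                seen.add(route.leaf)
    return (set(tree.nodes) | set(tree.leaves)) - seen


def enumerate_paths(
    tree: DecisionTree,
) -> list[tuple[tuple[tuple[str, str], ...], CausalityCategory]]:
    """All root-to-leaf paths as ((node id, answer), ...) with their category.

    Each leaf-directed route appears exactly once; depth-first in
    document order, so the listing is deterministic.
    """
    out: list[tuple[tuple[tuple[str, str], ...], CausalityCategory]] = []

    def walk(nid: str, prefix: tuple[tuple[str, str], ...]) -> None:
        node = tree.nodes[nid]
        for ans, route in node.routes.items():
            step = prefix + ((nid, ans),)
            if route.leaf is not None:
                out.append((step, tree.leaves[route.leaf].category))
            else:
                walk(route.node, step)

    walk(tree.root, ())
    return out


def validate_tree(tree: DecisionTree) -> TreeDiagnostics:
    """Run the semantic validation battery; diagnostics, never exceptions.

    Checks: acyclicity, route totality, reachability of every node and
    leaf, reachability of all four causality categories, and the
    Definite-gate rule (every path to a Definite leaf traverses a node
    tagged ``rechallenge_gate`` via that node's gate answer).
    """
    checks: list[CheckResult] = []

    cyc = _cycle_violations(tree)
    checks.append(CheckResult("acyclic", not cyc, tuple(cyc)))

    totality = [
        f"node {n.id!r} has fewer than two answer routes"
        for n in tree.nodes.values()
        if len(n.routes) < 2
    ]
    checks.append(CheckResult("totality", not totality, tuple(totality)))

    unreachable = _unreachable(tree)
    checks.append(
        CheckResult(
            "reachable",
            not unreachable,
            tuple(f"unreachable: {x}" for x in sorted(unreachable)),
        )
    )

    if cyc:  # paths are not enumerable on a cyclic graph
        checks.append(CheckResult("full_category_range", False, ("tree is cyclic",)))
        checks.append(CheckResult("definite_gate", False, ("tree is cyclic",)))
        return TreeDiagnostics(tuple(checks))

    paths = enumerate_paths(tree)
    seen_categories = {cat for _, cat in paths}
    missing = [c.label for c in CausalityCategory if c not in seen_categories]
    checks.append(
        CheckResult(
            "full_category_range",
            not missing,
            tuple(f"no reachable leaf for category {m}" for m in missing),
        )
    )

    gate_failures = []
    for path, cat in paths:
        if cat is not CausalityCategory.DEFINITE:
            continue
        gated = any(
            tree.nodes[nid].tags.get(GATE_TAG) == ans for nid, ans in path
        )
        if not gated:
            gate_failures.append(
                "Definite reachable without an affirmative re-challenge/previous-"
                f"reaction answer: path {' -> '.join(f'{n}={a}' for n, a in path)}"
            )
    checks.append(CheckResult("definite_gate", not gate_failures, tuple(gate_failures)))

    return TreeDiagnostics(tuple(checks))


def assess(tree: DecisionTree, answers: Mapping[str, str]) -> LiverpoolAssessment:
    """Traverse the tree with the given per-node answers.

    Only nodes actually visited need an answer; answers to off-path
    nodes are ignored. Missing or disallowed answers raise
    :class:`AssessmentError` naming the node and its prompt.
    """
    path: list[tuple[str, str]] = []
    nid = tree.root
    while True:
        node = tree.nodes[nid]
        if node.id not in answers:
            raise AssessmentError(
                f"no answer for visited node {node.id!r} ({node.prompt!r})"
            )
        ans = str(answers[node.id]).strip().lower()
        if ans not in node.routes:
            raise AssessmentError(
                f"answer {answers[node.id]!r} not allowed at node {node.id!r} "
                f"({node.prompt!r}); allowed: {sorted(node.routes)}"
            )
        path.append((node.id, ans))
        route = node.routes[ans]
        if route.leaf is not None:
            return LiverpoolAssessment(
                category=tree.leaves[route.leaf].category, path=tuple(path)
            )
        nid = route.node


def default_tree() -> DecisionTree:
    """The packaged Liverpool instrument."""
    doc = json.loads(
        resources.files("adrcat.data").joinpath("liverpool_tree.json").read_text()
    )
    return load_tree(doc)
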