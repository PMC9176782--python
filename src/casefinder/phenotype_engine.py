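"""Declarative rule engine for SNOMED code and free-text keyword matching.

A case-finding rule set is data, not code: a YAML document declares named
*components* — boolean expressions over two kinds of atoms — and named
*algorithm versions*, which are boolean expressions over component
references.  Two atom kinds exist:

``code``
    A SNOMED literal, optionally ending in ``*`` for a prefix match, bound
    to one axis (morphology ``M-`` or topography ``T-``).  An atom fires if
    ANY code of that axis on the record matches.

``keyword``
    A free-text keyword with optional wildcards, searched in the record's
    diagnosis field only.  ``*core*`` matches as a substring, ``core*``
    matches any token starting with the core, a bare ``core`` requires an
    exact token.  Text and keyword are case-folded, diacritic-stripped and
    whitespace-collapsed before matching, so Italian clinical text with
    inconsistent accents and casing matches reliably.

The shipped rule set ``nsclc_tuscany.rules`` encodes the NSCLC definition
for Italian pathology registries: an inclusion intersection of a
morphology component (listed NSCLC histology codes, or any ``M-8*`` code
accompanied by one of four histology keywords) and a chest-topography
component (``T-2*`` or the lung/bronchus keywords), refined by exclusion
components for neuroendocrine morphology (``M-82463``), upper-airway
topography (``T-21*``–``T-25*``) and unspecified respiratory topography
(``T-20*``).  Three versions are defined; the second modification (which
keeps unspecified-respiratory records but drops upper-airway and
neuroendocrine ones) is the final version.

Exclusion semantics are any-match: a single excluded code anywhere on the
record vetoes it, even when an included code co-occurs.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

import yaml

from .registry_model import PathologyRecord

__all__ = [
    "RuleConfigError",
    "CodePattern",
    "KeywordPattern",
    "And",
    "Or",
    "Not",
    "ComponentRef",
    "Component",
    "AlgorithmVersion",
    "RuleSet",
    "normalize_text",
    "match_code",
    "match_keyword",
    "evaluate_component",
    "evaluate_algorithm",
    "load_ruleset",
    "default_ruleset",
    "DEFAULT_RULES_RESOURCE",
]

DEFAULT_RULES_RESOURCE = "nsclc_tuscany.rules"

_AXES = ("morphology", "topography")
_WS_RE = re.compile(r"\s+")
_TOKEN_RE = re.compile(r"\w+")


class RuleConfigError(ValueError):
    """A rule-set document is malformed or internally inconsistent."""


def normalize_text(raw: str) -> str:
    """Case-fold, strip diacritics and collapse whitespace."""
    decomposed = unicodedata.normalize("NFKD", raw)
    stripped = "".join(ch for ch in decomposed if not unicodedata.combining(ch))
    return _WS_RE.sub(" ", stripped.casefold()).strip()


# ---------------------------------------------------------------------------
# Atoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CodePattern:
    """SNOMED code literal, optionally ``*``-suffixed for prefix matching."""

    literal: str
    axis: str

    def __post_init__(self) -> None:
        if not self.literal:
            raise RuleConfigError("code pattern literal must be non-empty")
        if "*" in self.literal[:-1]:
            raise RuleConfigError(
                f"code pattern {self.literal!r}: '*' may only be the final character"
            )
        if self.axis not in _AXES:
            raise RuleConfigError(f"code axis must be one of {_AXES}, got {self.axis!r}")

    def matches(self, code: str) -> bool:
        code = code.strip().upper()
        literal = self.literal.upper()
        if literal.endswith("*"):
            return code.startswith(literal[:-1])
        return code == literal


@dataclass(frozen=True)
class KeywordPattern:
    """Free-text keyword with wildcard-derived match mode."""

    raw: str

    def __post_init__(self) -> None:
        core = self.raw.strip("*")
        if not core:
            raise RuleConfigError(f"keyword pattern {self.raw!r} has an empty core")
        if self.raw.startswith("*") and not self.raw.endswith("*"):
            raise RuleConfigError(
                f"keyword pattern {self.raw!r}: leading '*' requires a trailing '*'"
            )

    @property
    def match_mode(self) -> str:
        if self.raw.startswith("*") and self.raw.endswith("*"):
            return "substring"
        if self.raw.endswith("*"):
            return "prefix"
        return "exact"

    @property
    def core(self) -> str:
        return normalize_text(self.raw.strip("*"))

    def matches(self, text: str) -> bool:
        return match_keyword(text, self)


def match_code(code: str, pattern: CodePattern) -> bool:
    """True iff ``code`` equals the literal or, with a trailing ``*``, starts with it."""
    return pattern.matches(code)


def match_keyword(text: str, pattern: KeywordPattern) -> bool:
    """Match one keyword against free text under the pattern's wildcard mode."""
    norm = normalize_text(text)
    core = pattern.core
    mode = pattern.match_mode
    if mode == "substring":
        return core in norm
    tokens = _TOKEN_RE.findall(norm)
    if mode == "prefix":
        return any(tok.startswith(core) for tok in tokens)
    return core in tokens


# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class And:
    children: tuple["Expression", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise RuleConfigError("AND node requires at least one child")


@dataclass(frozen=True)
class Or:
    children: tuple["Expression", ...]

    def __post_init__(self) -> None:
        if not self.children:
            raise RuleConfigError("OR node requires at least one child")


@dataclass(frozen=True)
class Not:
    child: "Expression"


@dataclass(frozen=True)
class ComponentRef:
    name: str


Expression = Union[CodePattern, KeywordPattern, And, Or, Not, ComponentRef]


@dataclass(frozen=True)
class Component:
    """Named boolean expression over code and keyword atoms."""

    name: str
    expression: Expression
    criterion: str = "inclusion"  # informational: inclusion vs exclusion role


@dataclass(frozen=True)
class AlgorithmVersion:
    """Named boolean expression over components, with its resolution context."""

    name: str
    expression: Expression
    final: bool = False
    components: Mapping[str, Component] = field(default_factory=dict, compare=False)


class _RecordView:
    """Pre-normalized view of a record, shared across atoms of one evaluation."""

    __slots__ = ("codes", "text", "tokens")

    def __init__(self, record: PathologyRecord) -> None:
        self.codes = {
            "morphology": [c.strip().upper() for c in record.morphology_codes],
            "topography": [c.strip().upper() for c in record.topography_codes],
        }
        self.text = normalize_text(record.diagnosis_text)
        self.tokens = _TOKEN_RE.findall(self.text)


def _eval(expr: Expression, view: _RecordView, components: Mapping[str, Component]) -> bool:
    if isinstance(expr, CodePattern):
        return any(expr.matches(code) for code in view.codes[expr.axis])
    if isinstance(expr, KeywordPattern):
        core = expr.core
        mode = expr.match_mode
        if mode == "substring":
            return core in view.text
        if mode == "prefix":
            return any(tok.startswith(core) for tok in view.tokens)
        return core in view.tokens
    if isinstance(expr, And):
        return all(_eval(c, view, components) for c in expr.children)
    if isinstance(expr, Or):
        return any(_eval(c, view, components) for c in expr.children)
    if isinstance(expr, Not):
        return not _eval(expr.child, view, components)
    if isinstance(expr, ComponentRef):
        try:
            component = components[expr.name]
        except KeyError:
            raise RuleConfigError(f"unresolved component reference {expr.name!r}") from None
        return _eval(component.expression, view, components)
    raise RuleConfigError(f"unknown expression node {expr!r}")


def evaluate_component(record: PathologyRecord, component: Component) -> bool:
    """Evaluate one component against one record.

    Code atoms fire if any code of the matching axis matches; keyword atoms
    are searched in the diagnosis field only.
    """
    return _eval(component.expression, _RecordView(record), {})


def evaluate_algorithm(record: PathologyRecord, version: AlgorithmVersion) -> bool:
    """Record-level flag for one algorithm version."""
    return _eval(version.expression, _RecordView(record), version.components)


# ---------------------------------------------------------------------------
# Rule-set loading
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RuleSet:
    components: Mapping[str, Component]
    algorithms: Mapping[str, AlgorithmVersion]

    @property
    def final_version(self) -> AlgorithmVersion:
        finals = [a for a in self.algorithms.values() if a.final]
        if len(finals) != 1:
            raise RuleConfigError("rule set must flag exactly one final version")
        return finals[0]

    def evaluate(self, record: PathologyRecord, algorithm: str) -> bool:
        return evaluate_algorithm(record, self.algorithms[algorithm])

    def flag_records(self, records: Iterable[PathologyRecord]) -> "pd.DataFrame":
        """One boolean column per algorithm version, indexed by record_id."""
        import pandas as pd

        names = list(self.algorithms)
        rows = {}
        for record in records:
            view = _RecordView(record)
            rows[record.record_id] = [
                _eval(self.algorithms[n].expression, view, self.algorithms[n].components)
                for n in names
            ]
        return pd.DataFrame.from_dict(rows, orient="index", columns=names)


def _parse_expression(node: object, where: str, allow: set[str]) -> Expression:
    if not isinstance(node, dict) or len(node) != 1:
        raise RuleConfigError(f"{where}: expression node must be a single-key mapping, got {node!r}")
    (key, value), = node.items()
    if key in ("all", "any"):
        if not isinstance(value, list):
            raise RuleConfigError(f"{where}: '{key}' expects a list of children")
        children = tuple(
            _parse_expression(child, f"{where}.{key}[{i}]", allow)
            for i, child in enumerate(value)
        )
        return And(children) if key == "all" else Or(children)
    if key == "not":
        return Not(_parse_expression(value, f"{where}.not", allow))
    if key == "code":
        if "code" not in allow:
            raise RuleConfigError(f"{where}: code atoms are not allowed here")
        if not isinstance(value, dict) or set(value) != {"axis", "pattern"}:
            raise RuleConfigError(f"{where}: code atom needs 'axis' and 'pattern'")
        return CodePattern(literal=str(value["pattern"]), axis=str(value["axis"]))
    if key == "keyword":
        if "keyword" not in allow:
            raise RuleConfigError(f"{where}: keyword atoms are not allowed here")
        return KeywordPattern(raw=str(value))
    if key == "component":
        if "component" not in allow:
            raise RuleConfigError(f"{where}: component references are not allowed here")
        return ComponentRef(name=str(value))
    raise RuleConfigError(f"{where}: unknown node kind {key!r}")


def _component_refs(expr: Expression) -> set[str]:
    if isinstance(expr, ComponentRef):
        return {expr.name}
    if isinstance(expr, (And, Or)):
        return set().union(*(_component_refs(c) for c in expr.children))
    if isinstance(expr, Not):
        return _component_refs(expr.child)
    return set()


def load_ruleset(source: str | Path | Mapping) -> RuleSet:
    """Load a rule set from a YAML path/string or an already-parsed mapping.

    The shipped default reproduces the three NSCLC algorithm versions and
    their five components exactly.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        text = Path(source).read_text(encoding="utf-8") if Path(str(source)).exists() else str(source)
        doc = yaml.safe_load(text)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise RuleConfigError("rule-set document must be a mapping")

    components: dict[str, Component] = {}
    for name, spec in (doc.get("components") or {}).items():
        if not isinstance(spec, dict) or "expression" not in spec:
            raise RuleConfigError(f"component {name!r}: missing 'expression'")
        expr = _parse_expression(
            spec["expression"], f"component {name!r}", allow={"code", "keyword"}
        )
        components[name] = Component(
            name=name, expression=expr, criterion=str(spec.get("criterion", "inclusion"))
        )

    algorithms: dict[str, AlgorithmVersion] = {}
    for name, spec in (doc.get("algorithms") or {}).items():
        if not isinstance(spec, dict) or "expression" not in spec:
            raise RuleConfigError(f"algorithm {name!r}: missing 'expression'")
        expr = _parse_expression(spec["expression"], f"algorithm {name!r}", allow={"component"})
        unresolved = _component_refs(expr) - set(components)
        if unresolved:
            raise RuleConfigError(
                f"algorithm {name!r} references undefined component(s): {sorted(unresolved)}"
            )
        algorithms[name] = AlgorithmVersion(
            name=name,
            expression=expr,
            final=bool(spec.get("final", False)),
            components=components,
        )
    return RuleSet(components=components, algorithms=algorithms)


def default_ruleset() -> RuleSet:
    """The shipped NSCLC rule set for Italian SNOMED pathology registries."""
    text = resources.files("casefinder.data").joinpath(DEFAULT_RULES_RESOURCE).read_text("utf-8")
    return load_ruleset(yaml.safe_load(text))
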