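"""Rule-based classification of free-text phenotypes into NDD categories.

Source databases report conditions as free text of wildly varying style
("Autism Spectrum Disorder", "mental retardation, autosomal dominant 21",
"SEIZURES"). A configurable terminology rule set maps each record's
phenotype strings onto the categories used for the catalog:

    CRD  - CTCF-related (neurodevelopmental) disorder, incl. legacy MRD21
    ID   - intellectual disability
    DD   - developmental disorder / delay
    IGD  - inborn genetic disease
    EP   - epilepsy
    ASD  - autism spectrum disorder
    ANS  - abnormality of the nervous system
    NON_NDD  - explicitly non-NDD conditions (e.g. breast cancer)
    CONTROL  - variant observed in unaffected sequencing controls

Matching is token-based: patterns and texts are lowercased, punctuation is
stripped and whitespace collapsed, and a pattern matches when its token
sequence appears contiguously in the text — so the short code "crd" matches
the token "CRD" but not "crdX". When several categories match, the
highest-priority (lowest number) wins: CRD outranks everything because it is
the definitive diagnosis; the remaining order descends in specificity and is
config-overridable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import yaml

NDD_CATEGORIES = ("CRD", "ASD", "DD", "EP", "ID", "IGD", "ANS")
ALL_CATEGORIES = NDD_CATEGORIES + ("NON_NDD", "CONTROL")

UNKNOWN = "UNKNOWN"
NO_PHENOTYPE_DATA = "NO_PHENOTYPE_DATA"

# Lower number = higher priority when several categories match.
DEFAULT_PRIORITY = {
    "CRD": 0, "ASD": 1, "EP": 2, "ID": 3, "DD": 4, "IGD": 5, "ANS": 6,
    "NON_NDD": 7, "CONTROL": 8,
}


class RuleConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TermRule:
    pattern: str
    category: str
    priority: int

    def __post_init__(self) -> None:
        if not self.pattern.strip():
            raise RuleConfigError("empty rule pattern")
        if self.category not in ALL_CATEGORIES:
            raise RuleConfigError(f"unknown category {self.category!r}")


def _normalize(text: str) -> tuple[str, ...]:
    text = re.sub(r"[^\w\s]", " ", text.lower())
    return tuple(text.split())


def _contains_tokens(haystack: tuple[str, ...], needle: tuple[str, ...]) -> bool:
    n = len(needle)
    if n == 0 or n > len(haystack):
        return False
    return any(haystack[i : i + n] == needle for i in range(len(haystack) - n + 1))


# Default terminology: catalog screening terms, legacy CRD synonyms, the
# explicit non-NDD exclusions, and control markers. The HPO clinical-feature
# list for CRD is user-supplied via config (slot: category ANS or CRD).
DEFAULT_TERMS: dict[str, list[str]] = {
    "CRD": [
        "CTCF related neurodevelopmental disorder",
        "CTCF-related disorder",
        "CTCF related disorder",
        "CRD",
        "Mental retardation, autosomal dominant 21",
        "MRD21",
        "intellectual disability-feeding difficulties-developmental delay-microcephaly syndrome",
    ],
    "ID": ["intellectual disability", "intellectual developmental disorder"],
    "DD": [
        "developmental disorder",
        "developmental delay",
        "global developmental delay",
        "developmental disability",
    ],
    "IGD": ["inborn genetic disease", "inborn genetic diseases"],
    "EP": ["epilepsy", "seizure", "seizures", "epileptic encephalopathy"],
    "ASD": ["autism spectrum disorder", "autism", "autistic behavior", "ASD"],
    "ANS": [
        "abnormality of the nervous system",
        "congenital nervous system disorder",
        "abnormality of nervous system",
    ],
    "NON_NDD": [
        "mammary neoplasms",
        "mammary neoplasm",
        "breast cancer",
        "acute megakaryoblastic leukemia",
        "congenital diaphragmatic hernia",
        "not specified",
    ],
    "CONTROL": ["control", "controls", "detected in controls", "healthy control"],
}


@dataclass
class RuleSet:
    rules: list[TermRule]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for rule in self.rules:
            key = " ".join(_normalize(rule.pattern))
            if key in seen and seen[key] != rule.category:
                raise RuleConfigError(
                    f"pattern {rule.pattern!r} mapped to both "
                    f"{seen[key]} and {rule.category}"
                )
            seen[key] = rule.category

    @property
    def categories(self) -> set[str]:
        return {r.category for r in self.rules}


def load_rules(config: Optional[dict | str | Path] = None) -> RuleSet:
    """Build a rule set from the default terminology plus optional config.

    ``config`` may be a mapping {category: [patterns]} (or a YAML file of the
    same shape, optionally with a "priority" mapping); an explicit empty
    mapping {} yields an empty rule set.
    """
    if config is None:
        terms: dict = dict(DEFAULT_TERMS)
        priority = dict(DEFAULT_PRIORITY)
    else:
        if isinstance(config, (str, Path)):
            config = yaml.safe_load(Path(config).read_text()) or {}
        config = dict(config)
        priority = {**DEFAULT_PRIORITY, **config.pop("priority", {})}
        if config.pop("extend_defaults", False):
            terms = {k: list(v) for k, v in DEFAULT_TERMS.items()}
            for cat, patterns in config.items():
                terms.setdefault(cat, []).extend(patterns)
        else:
            terms = config
    rules = [
        TermRule(pattern, category, priority.get(category, 99))
        for category, patterns in terms.items()
        for pattern in patterns
    ]
    return RuleSet(rules)


def classify(
    texts: Sequence[str], rules: RuleSet
) -> tuple[str, list[str]]:
    """Classify a record's phenotype strings.

    Returns (category, matched_patterns). All matching rules are collected;
    the final category is the highest-priority match. No match over nonempty
    text gives UNKNOWN; empty/absent text gives NO_PHENOTYPE_DATA.
    """
    tokenized = [_normalize(t) for t in texts if t and t.strip()]
    if not tokenized:
        return NO_PHENOTYPE_DATA, []
    matches: list[TermRule] = []
    for rule in rules.rules:
        needle = _normalize(rule.pattern)
        if any(_contains_tokens(hay, needle) for hay in tokenized):
            matches.append(rule)
    if not matches:
        return UNKNOWN, []
    best = min(matches, key=lambda r: r.priority)
    return best.category, sorted({r.pattern for r in matches})


def is_ndd(category: str) -> bool:
    """True exactly for the qualifying NDD categories."""
    return category in NDD_CATEGORIES
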