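"""Rule-table loading and matching.

The clinical constants and decision tables live in a human-editable YAML
file (``data/rules.yaml``), one row per rule with a stable id and a
provenance tag. This module loads the table, offers first-match lookup
over a patient-classification context, and validates completeness: every
reachable classification must match exactly one row in each decision
section.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Iterator, Mapping, Optional

import yaml

from .model import CopdStage, Phenotype, SarcopeniaLevel


class RuleTableError(ValueError):
    """Malformed or incomplete rule table."""


#: Phenotype branches the rule base defines. obesity_3 is routed onto the
#: obesity_2 branch (with a warning) before matching.
RULE_PHENOTYPES = (
    Phenotype.underweight,
    Phenotype.normal_weight,
    Phenotype.overweight,
    Phenotype.obesity_1,
    Phenotype.obesity_2,
)


def rule_phenotype(phenotype: Phenotype) -> Phenotype:
    """Map a phenotype to the rule branch that handles it."""
    if phenotype is Phenotype.obesity_3:
        return Phenotype.obesity_2
    return phenotype


def _matches(when: Mapping[str, Any], ctx: Mapping[str, Any]) -> bool:
    for key, want in when.items():
        have = ctx[key]
        if isinstance(want, (list, tuple)):
            if have not in want:
                return False
        elif have != want:
            return False
    return True


@dataclass(frozen=True)
class RuleBase:
    """Parsed rule table."""

    raw: Mapping[str, Any]

    # -- plain sections ---------------------------------------------------
    @property
    def constants(self) -> Mapping[str, Any]:
        return self.raw["constants"]

    @property
    def cutoffs(self) -> Mapping[str, Any]:
        return self.raw["cutoffs"]

    def section(self, *path: str) -> Any:
        node: Any = self.raw
        for key in path:
            node = node[key]
        return node

    # -- decision tables --------------------------------------------------
    def match(self, rows: list[Mapping[str, Any]], ctx: Mapping[str, Any]) -> Mapping[str, Any]:
        for row in rows:
            if _matches(row.get("when", {}), ctx):
                return row
        raise RuleTableError(f"no rule matches context {dict(ctx)}")

    def match_factor(self, ctx: Mapping[str, Any]) -> Mapping[str, Any]:
        return self.match(self.raw["energy"]["correction_factors"], ctx)

    def match_protein(self, ctx: Mapping[str, Any]) -> Mapping[str, Any]:
        return self.match(self.raw["protein"]["rules"], ctx)

    def match_supplements(self, ctx: Mapping[str, Any]) -> Mapping[str, Any]:
        return self.match(self.raw["supplements"]["rules"], ctx)

    # -- completeness -----------------------------------------------------
    def validate_completeness(self) -> None:
        """Check every reachable context matches a row in each decision table.

        Raises :class:`RuleTableError` on the first gap. Conflicts cannot
        arise under first-match semantics, so the check is for coverage and
        for duplicate rule ids.
        """
        ids: list[str] = [
            row["id"]
            for rows in (
                self.raw["energy"]["correction_factors"],
                self.raw["protein"]["rules"],
                self.raw["supplements"]["rules"],
            )
            for row in rows
        ]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise RuleTableError(f"duplicate rule ids: {sorted(dupes)}")
        for ctx in iter_contexts():
            self.match_factor(ctx)
            self.match_protein(ctx)
            self.match_supplements(ctx)


def iter_contexts() -> Iterator[dict[str, Any]]:
    """Iterate every reachable (phenotype branch, stage, sarcopenia, cachexia)
    context; cachexia requires sarcopenia."""
    for phenotype, stage, level in itertools.product(
        RULE_PHENOTYPES, CopdStage, SarcopeniaLevel
    ):
        cach_options = (False,) if level is SarcopeniaLevel.none else (False, True)
        for cachectic in cach_options:
            yield {
                "phenotype": phenotype.value,
                "stage": stage.value,
                "sarcopenic": level is not SarcopeniaLevel.none,
                "sarcopenia_level": level.value,
                "cachectic": cachectic,
            }


_DEFAULT: Optional[RuleBase] = None


def load_rules(path: Optional[str | Path] = None) -> RuleBase:
    """Load a rule table from ``path`` or the packaged default, and validate it."""
    if path is None:
        text = resources.files("nutricopd.data").joinpath("rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    rb = RuleBase(raw=raw)
    rb.validate_completeness()
    return rb


def default_rules() -> RuleBase:
    """The packaged rule table (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_rules()
    return _DEFAULT
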