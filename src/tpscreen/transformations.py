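"""Transformation-candidate enumeration and the TP registry.

A suspect-screening workflow needs a list of plausible transformation-product
(TP) masses before it ever looks at a chromatogram.  Candidates are generated
by applying a small library of transformation rules (hydroxylation, oxidation,
halogen-to-hydroxyl substitution, ring/side-chain cleavages) to the neutral
parent formula, up to a configurable chain depth.  Elementary rules compose
freely; cleavage rules encode one-shot structural losses and may appear at
most once in a chain.

The registry holds the curated TPs of the two study drugs (haloperidol and
aripiprazole) with their published cation formulas, observed m/z, category and
isomer letters.  Masses listed without a structural description are shipped
but excluded from the default registry, which keeps the canonical counts at
14 formulas / 32 isomers (haloperidol) and 12 / 13 (aripiprazole).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .formula import (
    ELEMENTS,
    ElementalComposition,
    FormulaError,
    IonSpecies,
    ion_mz,
    parse_formula,
    ppm_error,
)

__all__ = [
    "TransformationRule",
    "SuspectCandidate",
    "TPRegistryEntry",
    "load_rules",
    "load_registry",
    "enumerate_candidates",
    "delta_between",
    "registry_reachability",
    "PROTON",
]

PROTON = parse_formula("H")

DRUGS = ("haloperidol", "aripiprazole")

#: Neutral parent formulas.
PARENT_FORMULA: dict[str, str] = {
    "haloperidol": "C21H23ClFNO2",
    "aripiprazole": "C23H27Cl2N3O2",
}


@dataclass(frozen=True)
class TransformationRule:
    """A formula delta: ``neutral -> neutral + add - remove``."""

    label: str
    add: ElementalComposition
    remove: ElementalComposition
    category: str = "d"
    elementary: bool = True

    def __post_init__(self) -> None:
        if self.add == self.remove:
            raise FormulaError(f"rule {self.label!r} has a null net delta")

    def apply(self, neutral: ElementalComposition) -> ElementalComposition | None:
        """Apply to a neutral formula; None when a count would go negative."""
        candidate = neutral + self.add
        if not candidate.contains(self.remove):
            return None
        return candidate - self.remove


@dataclass(frozen=True)
class SuspectCandidate:
    """A hypothesized TP: neutral formula plus the shortest rule chain."""

    parent: ElementalComposition
    rules: tuple[str, ...]
    neutral: ElementalComposition
    category: str

    @property
    def cation(self) -> ElementalComposition:
        return self.neutral + PROTON

    @property
    def mz(self) -> float:
        """Theoretical [M+H]+ m/z."""
        return ion_mz(IonSpecies(self.cation))


@dataclass(frozen=True)
class TPRegistryEntry:
    """A published TP: name, [M+H]+ formula, observed m/z, isomer letters."""

    name: str
    cation_formula: ElementalComposition | None
    observed_mz: float
    category: str
    isomers: tuple[tuple[str, float | None], ...]
    described: bool = True
    note: str = ""

    @property
    def neutral_formula(self) -> ElementalComposition | None:
        if self.cation_formula is None:
            return None
        return self.cation_formula - PROTON

    @property
    def theoretical_mz(self) -> float | None:
        if self.cation_formula is None:
            return None
        return ion_mz(IonSpecies(self.cation_formula))

    @property
    def mass_error_ppm(self) -> float | None:
        theo = self.theoretical_mz
        if theo is None:
            return None
        return ppm_error(self.observed_mz, theo)


def _read_tsv(path_or_name: str | Path) -> list[dict[str, str]]:
    """Read a shipped or user TSV, skipping '#' comment lines."""
    p = Path(path_or_name)
    if p.exists():
        text = p.read_text()
    else:
        text = (
            resources.files("tpscreen").joinpath(f"data/{path_or_name}").read_text()
        )
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return list(csv.DictReader(lines, delimiter="\t"))


def _parse_opt(text: str) -> ElementalComposition:
    return ElementalComposition() if text in ("-", "") else parse_formula(text)


def load_rules(drug_or_path: str | Path) -> list[TransformationRule]:
    """Load a rule set for a drug preset name or from a TSV path."""
    name = (
        f"rules_{drug_or_path}.tsv" if str(drug_or_path) in DRUGS else drug_or_path
    )
    rules = []
    for row in _read_tsv(name):
        rules.append(
            TransformationRule(
                label=row["label"],
                add=_parse_opt(row["add"]),
                remove=_parse_opt(row["remove"]),
                category=row["category"],
                elementary=row["elementary"] == "1",
            )
        )
    return rules


def load_registry(
    drug_or_path: str | Path, include_undescribed: bool = False
) -> list[TPRegistryEntry]:
    """Load the TP registry for a drug preset name or from a TSV path.

    By default only entries with a structural description are returned; the
    listed-but-undescribed masses are flagged with ``described=False`` and
    available via ``include_undescribed=True``.
    """
    name = (
        f"registry_{drug_or_path}.tsv"
        if str(drug_or_path) in DRUGS
        else drug_or_path
    )
    entries = []
    for row in _read_tsv(name):
        isomers = []
        for token in row["isomers"].split(","):
            letter, _, rt = token.partition("@")
            isomers.append((letter, float(rt) if rt else None))
        entry = TPRegistryEntry(
            name=row["name"],
            cation_formula=(
                None if row["cation_formula"] == "-" else parse_formula(row["cation_formula"])
            ),
            observed_mz=float(row["observed_mz"]),
            category=row["category"],
            isomers=tuple(isomers),
            described=row["described"] == "1",
            note=row.get("note", ""),
        )
        if entry.described or include_undescribed:
            entries.append(entry)
    return entries


def enumerate_candidates(
    parent: ElementalComposition,
    rules: Sequence[TransformationRule],
    max_steps: int,
) -> list[SuspectCandidate]:
    """Breadth-first enumeration of TP candidates up to ``max_steps`` rules.

    Candidates are deduplicated by neutral formula, each keeping the shortest
    rule chain that reaches it (ties broken by the lexicographically smallest
    chain of labels, making the result independent of rule ordering).  At most
    one non-elementary (cleavage) rule per chain.  Output sorted by
    theoretical m/z, then by Hill string.
    """
    if max_steps < 0:
        raise ValueError("max_steps must be >= 0")
    ordered = sorted(rules, key=lambda r: r.label)
    # state: neutral formula -> (chain, used_cleavage)
    best: dict[ElementalComposition, tuple[tuple[str, ...], bool]] = {
        parent: ((), False)
    }
    frontier = [(parent, (), False)]
    for _ in range(max_steps):
        new_frontier = []
        for neutral, chain, used in sorted(
            frontier, key=lambda t: t[1]
        ):
            for rule in ordered:
                if not rule.elementary and used:
                    continue
                nxt = rule.apply(neutral)
                if nxt is None:
                    continue
                new_chain = chain + (rule.label,)
                new_used = used or not rule.elementary
                prev = best.get(nxt)
                if prev is None or (
                    len(new_chain) < len(prev[0])
                    or (len(new_chain) == len(prev[0]) and new_chain < prev[0])
                ):
                    best[nxt] = (new_chain, new_used)
                    new_frontier.append((nxt, new_chain, new_used))
        frontier = new_frontier

    by_label = {r.label: r for r in ordered}

    def chain_category(chain: tuple[str, ...]) -> str:
        cats = [by_label[lbl].category for lbl in chain]
        for c in ("a", "b", "c"):
            if c in cats:
                return c
        return "d"

    out = [
        SuspectCandidate(
            parent=parent, rules=chain, neutral=neutral, category=chain_category(chain)
        )
        for neutral, (chain, _) in best.items()
    ]
    out.sort(key=lambda c: (c.mz, c.neutral.hill()))
    return out


def delta_between(
    parent: ElementalComposition, tp_neutral: ElementalComposition
) -> dict[str, int]:
    """Signed element delta such that parent + delta = tp_neutral."""
    return {
        el: tp_neutral[el] - parent[el]
        for el in ELEMENTS
        if tp_neutral[el] != parent[el]
    }


def registry_reachability(
    registry: Iterable[TPRegistryEntry],
    parent: ElementalComposition,
    rules: Sequence[TransformationRule],
    max_steps: int = 4,
) -> dict[str, tuple[bool, tuple[str, ...] | None]]:
    """For each registry entry, whether a rule chain reproduces its formula.

    Returns ``{name: (reachable, shortest_chain_or_None)}``.  Entries without
    a formula (undescribed masses) report unreachable.
    """
    candidates = {
        c.neutral: c.rules for c in enumerate_candidates(parent, rules, max_steps)
    }
    report: dict[str, tuple[bool, tuple[str, ...] | None]] = {}
    for entry in registry:
        neutral = entry.neutral_formula
        if neutral is not None and neutral in candidates:
            report[entry.name] = (True, candidates[neutral])
        else:
            report[entry.name] = (False, None)
    return report
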