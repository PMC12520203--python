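"""Suspect screening and MSn fragment annotation.

The annotation engine does four jobs:

* **Subformula assignment** - every MS2/MS3 centroid is matched against the
  exhaustive set of element-wise subformulas of its precursor, keeping those
  whose even-electron cation m/z falls inside a ppm tolerance and ranking
  them by mass error, ring-plus-double-bond plausibility and parsimony of
  heteroatom removal.
* **Neutral-loss closure** - a parent/child pair of assignments implies the
  loss formula (parent minus child); losses whose odd-valence atom count is
  odd are flagged as radical losses (e.g. loss of a chlorine atom).
* **Fragmentation trees** - MS3 peaks are assigned only against the best
  assignment of their MS2 precursor peak, so formulas are nested along every
  root-to-leaf path and losses sum telescopically.
* **Suspect screening** - extracted-ion chromatograms (default 50 ppm) are
  peak-picked per run, isomers are lettered A, B, C... in elution order, and
  a detection requires MS2 evidence (at least one assignable fragment) when
  tandem spectra exist for the dataset.  Chlorine count is inferred from the
  M+2/M (and M+4/M) intensity ratios against the closed-form chlorine
  pattern, and each detection receives an identification confidence level on
  the 1-5 scale used in nontarget screening (1 = confirmed by reference
  standard, 3 = tentative candidate with diagnostic MS2 evidence, 5 = exact
  mass only).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np

from .formula import (
    ELEMENTS,
    ELECTRON_MASS,
    MONOISOTOPIC_MASS,
    CL37_CL35_SHIFT,
    ElementalComposition,
    FormulaError,
    IonSpecies,
    MassMeasurement,
    ion_mz,
    ppm_error,
    rdbe,
)
from .spectra import LcMsRun, MsnSpectrum, extract_eic, pick_peaks
from .transformations import PROTON, SuspectCandidate, TPRegistryEntry

__all__ = [
    "FragmentAssignment",
    "FragmentationTree",
    "IsomerDetection",
    "AnnotatedTP",
    "assign_subformulas",
    "annotate_loss",
    "build_tree",
    "infer_cl_count",
    "screen_suspects",
    "assign_confidence_level",
]


@dataclass(frozen=True)
class FragmentAssignment:
    """One interpreted MSn peak: cation formula, mass error, neutral loss."""

    observed_mz: float
    formula: ElementalComposition
    ppm: float
    loss: ElementalComposition | None = None
    abundance_pct: float | None = None
    radical: bool = False

    @property
    def theoretical_mz(self) -> float:
        return ion_mz(IonSpecies(self.formula))


def _loss_is_radical(loss: ElementalComposition) -> bool:
    """A neutral fragment with an odd count of odd-valence atoms is a radical."""
    return (loss["H"] + loss["Cl"] + loss["F"] + loss["N"]) % 2 == 1


@lru_cache(maxsize=64)
def _subformula_table(counts: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """All element-wise subformula count vectors of a precursor + cation m/z."""
    axes = [np.arange(c + 1) for c in counts]
    grids = np.meshgrid(*axes, indexing="ij")
    table = np.stack([g.ravel() for g in grids], axis=1)
    masses = table @ np.array([MONOISOTOPIC_MASS[el] for el in ELEMENTS])
    return table, masses - ELECTRON_MASS


def assign_subformulas(
    precursor: ElementalComposition,
    fragment: MassMeasurement | float,
    tol_ppm: float = 10.0,
    allow_radical: bool = False,
    reference_ppm: float = 0.0,
) -> list[FragmentAssignment]:
    """Rank all subformulas of ``precursor`` matching a fragment m/z.

    Exhaustive over the product of per-element count ranges.  Candidates
    within ``tol_ppm`` of the even-electron cation m/z are ranked by mass
    error, then RDBE plausibility (-0.5 <= RDBE <= precursor RDBE + 1), then
    fewer heteroatoms removed from the precursor, with the Hill string as
    the final deterministic tie-break.

    Mass-error ranking is relative to ``reference_ppm``, the locally
    calibrated systematic error of the acquisition (Orbitrap mass errors are
    dominated by a per-spectrum calibration bias shared between precursor
    and fragments).  :func:`build_tree` estimates it from the precursor's
    own observed m/z; the default of 0 ranks by absolute error.

    ``allow_radical`` only affects the parity flag bookkeeping of downstream
    loss annotation; for singly charged cations the radical and
    even-electron interpretation of a formula share one m/z.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if precursor.is_empty:
        raise FormulaError("empty precursor composition")
    obs = (
        fragment.observed_mz if isinstance(fragment, MassMeasurement) else float(fragment)
    )
    table, mzs = _subformula_table(precursor.counts)
    sel = np.abs((obs - mzs) / mzs) * 1e6 <= tol_ppm
    sel &= table.sum(axis=1) > 0
    prec_rdbe = rdbe(precursor)
    hetero_idx = [i for i, el in enumerate(ELEMENTS) if el not in ("C", "H")]
    results = []
    for row, mz in zip(table[sel], mzs[sel]):
        comp = ElementalComposition(tuple(int(x) for x in row))
        loss = precursor - comp
        radical = _loss_is_radical(loss)
        # even-electron rule: an even-electron cation sheds closed-shell
        # neutrals; odd-parity (radical) losses are admitted only on request
        if radical and not allow_radical:
            continue
        err = (obs - mz) / mz * 1e6
        r = rdbe(comp)
        plausible = -0.5 <= r <= prec_rdbe + 1
        removals = sum(precursor.counts[i] - row[i] for i in hetero_idx)
        results.append(
            (
                (abs(err - reference_ppm), radical, not plausible, removals,
                 comp.hill()),
                FragmentAssignment(
                    observed_mz=obs,
                    formula=comp,
                    ppm=err,
                    loss=loss,
                    radical=radical,
                ),
            )
        )
    results.sort(key=lambda t: t[0])
    return [a for _, a in results]


def annotate_loss(
    parent: ElementalComposition | FragmentAssignment,
    child: ElementalComposition | FragmentAssignment,
) -> tuple[ElementalComposition, bool]:
    """Neutral loss between a parent and child assignment.

    Returns ``(loss_formula, radical_flag)``; the flag is set when the loss
    carries an unpaired electron (odd count of odd-valence atoms), as in the
    radical chlorine losses seen for dichlorinated TPs.  Raises
    :class:`~tpscreen.formula.NotASubformulaError` when the child is not a
    subformula of the parent.
    """
    p = parent.formula if isinstance(parent, FragmentAssignment) else parent
    c = child.formula if isinstance(child, FragmentAssignment) else child
    loss = p - c
    return loss, _loss_is_radical(loss)


@dataclass
class TreeNode:
    assignment: FragmentAssignment
    ms_level: int
    parent: int | None  # index into FragmentationTree.nodes


@dataclass
class FragmentationTree:
    """Nested subformula interpretation of one precursor's MSn spectra."""

    root: IonSpecies
    nodes: list[TreeNode] = field(default_factory=list)
    unassigned: list[tuple[int, float]] = field(default_factory=list)  # (level, mz)

    def paths(self) -> list[list[TreeNode]]:
        out = []
        children = {i: [] for i in range(len(self.nodes))}
        roots = []
        for i, node in enumerate(self.nodes):
            if node.parent is None:
                roots.append(i)
            else:
                children[node.parent].append(i)
        def walk(i, acc):
            acc = acc + [self.nodes[i]]
            if not children[i]:
                out.append(acc)
            for j in children[i]:
                walk(j, acc)
        for r in roots:
            walk(r, [])
        return out


class TreeBuildError(ValueError):
    pass


def build_tree(
    spectra: Sequence[MsnSpectrum],
    precursor: ElementalComposition,
    tol_ppm: float = 10.0,
    allow_radical: bool = False,
) -> FragmentationTree:
    """Assemble a loss-closed fragmentation tree from MS2/MS3 spectra.

    MS2 peaks are assigned against the precursor cation formula; each MS3
    spectrum is anchored to the best assignment of the MS2 peak matching its
    selected precursor m/z, and its peaks are assigned only as subformulas of
    that anchor.  Peaks with no assignment inside the tolerance are collected
    in ``unassigned`` rather than discarded silently.
    """
    tree = FragmentationTree(root=IonSpecies(precursor))
    ms2 = [sp for sp in spectra if sp.ms_level == 2]
    ms3 = [sp for sp in spectra if sp.ms_level == 3]
    if not ms2 and ms3:
        raise TreeBuildError("MS3 spectra present without any MS2 anchor")
    ms2_index: list[tuple[float, int]] = []  # (observed mz, node index)
    root_mz = ion_mz(tree.root)
    for sp in ms2:
        # per-spectrum calibration bias, estimated from the precursor itself
        ref = ppm_error(sp.precursor_path[0], root_mz)
        for peak in sp.peaks:
            hits = assign_subformulas(
                precursor, MassMeasurement(peak.mz, peak.intensity), tol_ppm,
                allow_radical=allow_radical, reference_ppm=ref,
            )
            if not hits:
                tree.unassigned.append((2, peak.mz))
                continue
            tree.nodes.append(TreeNode(hits[0], 2, None))
            ms2_index.append((peak.mz, len(tree.nodes) - 1))
    for sp in ms3:
        sel = sp.precursor_path[-1]
        anchors = [
            (abs(mz - sel), idx) for mz, idx in ms2_index
            if abs(mz - sel) / sel * 1e6 <= max(tol_ppm, 50.0)
        ]
        if not anchors:
            raise TreeBuildError(
                f"no assigned MS2 peak matches MS3 precursor m/z {sel:.4f}"
            )
        _, anchor_idx = min(anchors)
        anchor = tree.nodes[anchor_idx].assignment
        anchor_formula = anchor.formula
        for peak in sp.peaks:
            hits = assign_subformulas(
                anchor_formula, MassMeasurement(peak.mz, peak.intensity), tol_ppm,
                allow_radical=allow_radical, reference_ppm=anchor.ppm,
            )
            if not hits:
                tree.unassigned.append((3, peak.mz))
                continue
            tree.nodes.append(TreeNode(hits[0], 3, anchor_idx))
    return tree


#: Closed-form chlorine isotope ratios relative to the monoisotopic peak.
_CL_M2 = 0.2423 / 0.7577
_CL_RATIOS = {
    0: (0.0, 0.0),
    1: (_CL_M2, 0.0),
    2: (2 * _CL_M2, _CL_M2 ** 2),
}


def infer_cl_count(
    m_intensity: float,
    m2_intensity: float,
    m4_intensity: float | None = None,
) -> tuple[int, float]:
    """Chlorine count (0, 1 or 2) from M+2/M (and optionally M+4/M) ratios.

    Compares the observed ratios with the binomial chlorine pattern and
    returns the argmin together with its absolute ratio deviation (the match
    score; smaller is better).
    """
    if m_intensity <= 0:
        raise ValueError("monoisotopic intensity must be positive")
    r2 = m2_intensity / m_intensity
    r4 = None if m4_intensity is None else m4_intensity / m_intensity
    best = None
    for n, (ref2, ref4) in _CL_RATIOS.items():
        dev = abs(r2 - ref2)
        if r4 is not None:
            dev += abs(r4 - ref4)
        if best is None or dev < best[1]:
            best = (n, dev)
    return best


@dataclass(frozen=True)
class IsomerDetection:
    letter: str
    rt: float
    apex_intensity: float
    area: float


@dataclass
class AnnotatedTP:
    """One screened suspect with its isomer-resolved detections."""

    name: str
    cation_formula: ElementalComposition
    theoretical_mz: float
    category: str
    isomers: list[IsomerDetection]
    ms2_evidence: list[FragmentAssignment]
    cl_count: int | None
    confidence_level: int

    @property
    def n_isomers(self) -> int:
        return len(self.isomers)


def assign_confidence_level(
    has_ms2_evidence: bool,
    standard_match: bool = False,
    formula_unique: bool = True,
) -> int:
    """Identification confidence on the 1-5 nontarget-screening scale.

    Retention time + MS2 match to an authentic standard gives level 1;
    diagnostic MS2 evidence without a standard gives level 3 (tentative
    candidate); exact mass with a unique formula gives 4; exact mass alone
    gives 5.  Level 2 (library match) is not produced by this workflow.
    """
    if standard_match and has_ms2_evidence:
        return 1
    if has_ms2_evidence:
        return 3
    return 4 if formula_unique else 5


def _normalize_suspect(
    suspect: TPRegistryEntry | SuspectCandidate,
) -> tuple[str, ElementalComposition, float, str]:
    if isinstance(suspect, TPRegistryEntry):
        if suspect.cation_formula is None:
            raise ValueError(f"suspect {suspect.name} has no formula")
        return (
            suspect.name,
            suspect.cation_formula,
            suspect.theoretical_mz,
            suspect.category,
        )
    cation = suspect.cation
    return (f"TP_{cation.hill()}", cation, suspect.mz, suspect.category)


def _cluster_apexes(
    picked: list[tuple[float, float, float]], rt_cluster: float
) -> list[tuple[float, float, float]]:
    """Merge apexes from different runs that share a retention time."""
    if not picked:
        return []
    picked = sorted(picked)
    clusters = []
    current = [picked[0]]
    for item in picked[1:]:
        if item[0] - current[-1][0] <= rt_cluster:
            current.append(item)
        else:
            clusters.append(current)
            current = [item]
    clusters.append(current)
    out = []
    for group in clusters:
        best = max(group, key=lambda t: t[1])
        out.append(best)
    return out


def screen_suspects(
    runs: Sequence[LcMsRun],
    suspects: Sequence[TPRegistryEntry | SuspectCandidate],
    screen_tol_ppm: float = 50.0,
    frag_tol_ppm: float = 10.0,
    detection_threshold: float = 0.0,
    noise_multiple: float = 3.0,
    require_ms2: bool | str = "auto",
    rt_cluster_min: float = 0.1,
    standards: Iterable[str] = (),
) -> list[AnnotatedTP]:
    """Screen a set of runs for suspect TPs and annotate the detections.

    For every suspect the EIC at the theoretical [M+H]+ m/z is extracted from
    each run (``screen_tol_ppm`` window) and peak-picked above
    ``max(detection_threshold, noise_multiple x median EIC level)``; apexes
    from different runs are clustered on retention time, and the clusters are
    lettered A, B, C... in elution order.  When the dataset contains tandem
    spectra (``require_ms2='auto'``), an apex only counts as a detection if
    an MS2 scan with a matching precursor m/z and retention time yields at
    least one fragment assignable as a subformula of the suspect at
    ``frag_tol_ppm``.  Chlorine count is inferred from the M+2 (and M+4)
    companion peaks in the MS1 scan at the strongest apex.  Suspects named in
    ``standards`` have an authentic reference standard available and are
    eligible for confidence level 1.  Output is sorted by theoretical m/z;
    suspects with no surviving detection are omitted.
    """
    any_ms2 = any(run.msn_scans(level=2) for run in runs)
    need_ms2 = any_ms2 if require_ms2 == "auto" else bool(require_ms2)
    standards = set(standards)
    results = []
    for suspect in suspects:
        name, cation, theo_mz, category = _normalize_suspect(suspect)
        picked_all: list[tuple[float, float, float]] = []
        for run in runs:
            eic = extract_eic(run, theo_mz, screen_tol_ppm)
            if len(eic) == 0:
                continue
            noise = float(np.median(eic.intensities))
            threshold = max(detection_threshold, noise_multiple * noise)
            for pk in pick_peaks(eic, min_intensity=threshold):
                picked_all.append((pk.rt, pk.apex_intensity, pk.area))
        clusters = _cluster_apexes(picked_all, rt_cluster_min)
        if not clusters:
            continue

        # candidate MS2 evidence spectra for this suspect
        evidence_scans = []
        for run in runs:
            for sp in run.msn_scans(level=2):
                prec = sp.precursor_path[0]
                if abs(prec - theo_mz) / theo_mz * 1e6 <= screen_tol_ppm:
                    evidence_scans.append(sp)

        detections: list[IsomerDetection] = []
        best_evidence: list[FragmentAssignment] = []
        for rt, apex, area in clusters:
            assigned: list[FragmentAssignment] = []
            for sp in evidence_scans:
                if abs(sp.rt_min - rt) > rt_cluster_min:
                    continue
                for peak in sp.peaks:
                    hits = assign_subformulas(
                        cation,
                        MassMeasurement(peak.mz, peak.intensity),
                        frag_tol_ppm,
                    )
                    if hits:
                        assigned.append(hits[0])
            if need_ms2 and not assigned:
                continue
            detections.append(IsomerDetection("?", rt, apex, area))
            if len(assigned) > len(best_evidence):
                best_evidence = assigned
        if not detections:
            continue
        detections.sort(key=lambda d: d.rt)
        detections = [
            IsomerDetection(chr(ord("A") + i), d.rt, d.apex_intensity, d.area)
            for i, d in enumerate(detections)
        ]

        cl_count = _infer_cl_at_apex(runs, theo_mz, detections, screen_tol_ppm)
        level = assign_confidence_level(
            has_ms2_evidence=bool(best_evidence),
            standard_match=name in standards and bool(best_evidence),
        )
        results.append(
            AnnotatedTP(
                name=name,
                cation_formula=cation,
                theoretical_mz=theo_mz,
                category=category,
                isomers=detections,
                ms2_evidence=best_evidence,
                cl_count=cl_count,
                confidence_level=level,
            )
        )
    results.sort(key=lambda r: r.theoretical_mz)
    return results


def _infer_cl_at_apex(
    runs: Sequence[LcMsRun],
    theo_mz: float,
    detections: list[IsomerDetection],
    tol_ppm: float,
) -> int | None:
    """Chlorine count from the MS1 scan nearest the strongest detection."""
    top = max(detections, key=lambda d: d.apex_intensity)
    half = theo_mz * tol_ppm * 1e-6
    best_scan = None
    best_dt = None
    for run in runs:
        for sp in run.ms1_scans():
            m = sum(p.intensity for p in sp.peaks if abs(p.mz - theo_mz) <= half)
            if m <= 0:
                continue
            dt = abs(sp.rt_min - top.rt)
            if best_dt is None or dt < best_dt:
                best_dt, best_scan = dt, (sp, m)
    if best_scan is None:
        return None
    sp, m = best_scan
    m2 = sum(
        p.intensity
        for p in sp.peaks
        if abs(p.mz - (theo_mz + CL37_CL35_SHIFT)) <= half
    )
    m4 = sum(
        p.intensity
        for p in sp.peaks
        if abs(p.mz - (theo_mz + 2 * CL37_CL35_SHIFT)) <= half
    )
    n, _ = infer_cl_count(m, m2, m4)
    return n
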