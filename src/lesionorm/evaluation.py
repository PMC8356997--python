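"""Normalization-accuracy metrics and the two-arm study harness.

Accuracy is judged the way normalization quality is judged for group
analysis: source labels are pushed through the common space into the
target's native space and compared with the target's own labels by the
Jaccard coefficient, averaged over regions.  Lesion-induced error is the
absolute difference between a lesioned pair's score and the matched clean
pair's score.  Cohorts without label protocols are scored by normalized
mutual information between each warped image and the space image within
brain voxels; the dependence of that accuracy on lesion size is summarized
with Pearson's r, and correlations between methods are compared with
Steiger's test for dependent correlations.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .lesion_sim import VirtualCohort, otsu_brain_mask
from .registration import RegistrationConfig, syn_register
from .template_builder import TemplateConfig, build_template
from .volumes import (
    DiffeomorphicTransform,
    GeometryError,
    ImageVolume,
    LabelVolume,
    LesionMask,
    ValidationError,
    resample,
)

__all__ = [
    "OverlapRecord",
    "AccuracyTable",
    "jaccard",
    "pairwise_overlap",
    "accuracy_difference",
    "entropy",
    "nmi",
    "lesion_size",
    "size_dependence",
    "compare_dependent_correlations",
    "run_experiment",
    "ExperimentReport",
]


@dataclass
class OverlapRecord:
    source_id: str
    target_id: str
    per_label_jaccard: dict
    mean_jaccard: float
    space: str = ""
    missing_labels: tuple = ()


@dataclass
class AccuracyTable:
    table: pd.DataFrame  # pair, method, jaccard_lesioned, jaccard_ground, abs_difference

    @property
    def mean_abs_difference(self) -> float:
        return float(self.table["abs_difference"].mean())

    @property
    def median_abs_difference(self) -> float:
        return float(self.table["abs_difference"].median())


# ---------------------------------------------------------------------------
# overlap metrics
# ---------------------------------------------------------------------------


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary sets (1.0 if both are empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise GeometryError("sets must share one grid")
    union = np.logical_or(a, b).sum()
    if union == 0:
        warnings.warn("both sets empty: Jaccard defined as 1.0")
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def pairwise_overlap(
    source: tuple,
    target: tuple,
    space: str = "",
    source_id: str = "source",
    target_id: str = "target",
) -> OverlapRecord:
    """Per-label Jaccard between source labels pushed through the common
    space into the target's native space and the target's own labels.

    ``source``/``target`` are ``(LabelVolume, DiffeomorphicTransform)``
    pairs where each transform was produced by registering that subject's
    image to the same common space (pull-back space -> subject).  Source
    labels are warped to the space with the source transform, then to the
    target's native grid with the inverse of the target transform, both
    with nearest-neighbour interpolation.  Labels present in only one
    volume score 0 and are flagged.
    """
    src_labels, src_t = source
    tgt_labels, tgt_t = target
    labels_in_space = resample(
        src_labels, src_t, src_t.geometry, interpolation="nearest"
    )
    warped = resample(
        labels_in_space, tgt_t, tgt_labels.geometry, interpolation="nearest",
        invert=True,
    )
    all_ids = sorted(warped.label_ids | tgt_labels.label_ids)
    per_label = {}
    missing = []
    for lid in all_ids:
        a = warped.data == lid
        b = tgt_labels.data == lid
        if not a.any() or not b.any():
            missing.append(lid)
            per_label[lid] = 0.0 if (a.any() or b.any()) else 1.0
        else:
            per_label[lid] = jaccard(a, b)
    mean = float(np.mean(list(per_label.values()))) if per_label else 1.0
    return OverlapRecord(
        source_id=source_id,
        target_id=target_id,
        per_label_jaccard=per_label,
        mean_jaccard=mean,
        space=space,
        missing_labels=tuple(missing),
    )


def accuracy_difference(lesioned_pairs, ground_pairs, method: str = "") -> AccuracyTable:
    """Per-pair |lesioned score - matched clean score| with summaries.

    ``ground_pairs`` is keyed by (source_id, target_id) of the *clean*
    images each lesioned image derives from; each lesioned pair must find
    its matched clean pair.
    """
    ground = {(r.source_id, r.target_id): r for r in ground_pairs}
    ground.update({(r.target_id, r.source_id): r for r in ground_pairs})
    rows = []
    missing = []
    for rec in lesioned_pairs:
        src_ctl = rec.source_id.split("+")[0]
        tgt_ctl = rec.target_id.split("+")[0]
        key = (src_ctl, tgt_ctl)
        if key not in ground:
            missing.append(key)
            continue
        g = ground[key]
        rows.append(
            {
                "pair": f"{rec.source_id}|{rec.target_id}",
                "method": method,
                "jaccard_lesioned": rec.mean_jaccard,
                "jaccard_ground": g.mean_jaccard,
                "abs_difference": abs(rec.mean_jaccard - g.mean_jaccard),
            }
        )
    if missing:
        raise ValidationError(f"unmatched lesioned pairs (no clean ground truth): {missing}")
    return AccuracyTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# information-theoretic metrics
# ---------------------------------------------------------------------------


def entropy(
    image: ImageVolume | np.ndarray,
    bins: int = 64,
    mask: np.ndarray | None = None,
    value_range: tuple | None = None,
) -> float:
    """Shannon entropy (bits) of the binned intensity distribution."""
    data = np.asarray(image.data if isinstance(image, ImageVolume) else image, float)
    vals = data[mask] if mask is not None else data.ravel()
    hist, _ = np.histogram(vals, bins=bins, range=value_range)
    p = hist / hist.sum()
    p = p[p > 0]
    if len(p) <= 1:
        return 0.0
    return float(-(p * np.log2(p)).sum())


def nmi(
    i1: ImageVolume | np.ndarray,
    i2: ImageVolume | np.ndarray,
    bins: int = 64,
    mask: np.ndarray | None = None,
) -> float:
    """Normalized mutual information (H1 + H2) / H12 over masked voxels.

    Symmetric, 2.0 for identical non-degenerate images, ~1.0 for
    independent binned intensities.  Binning is equal-width over each
    image's own masked range (the paper's formulation leaves binning
    open; 64 bins is the package default).
    """
    a = np.asarray(i1.data if isinstance(i1, ImageVolume) else i1, float)
    b = np.asarray(i2.data if isinstance(i2, ImageVolume) else i2, float)
    if a.shape != b.shape:
        raise GeometryError("images must share one grid")
    if mask is not None:
        av, bv = a[mask], b[mask]
    else:
        av, bv = a.ravel(), b.ravel()
    joint, _, _ = np.histogram2d(av, bv, bins=bins)
    p = joint / joint.sum()
    p1 = p.sum(axis=1)
    p2 = p.sum(axis=0)
    if (p1 > 0).sum() <= 1 or (p2 > 0).sum() <= 1:
        raise ValidationError("degenerate marginal distribution: NMI undefined")
    h1 = -(p1[p1 > 0] * np.log2(p1[p1 > 0])).sum()
    h2 = -(p2[p2 > 0] * np.log2(p2[p2 > 0])).sum()
    pj = p[p > 0]
    h12 = -(pj * np.log2(pj)).sum()
    return float((h1 + h2) / h12)


def lesion_size(mask: LesionMask) -> int:
    """Number of nonzero voxels in the lesion mask."""
    return int(mask.count())


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------


def size_dependence(accuracy, sizes):
    """Pearson correlation (with fitted line) of accuracy vs. lesion size."""
    x = np.asarray(sizes, dtype=float)
    y = np.asarray(accuracy, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValidationError("need >= 3 matched (accuracy, size) observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("accuracy/size values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return {"r": float(r), "p": float(p), "slope": float(slope), "intercept": float(intercept)}


def compare_dependent_correlations(
    r_jk: float, r_jh: float, r_kh: float, n: int, one_sided: bool = False
):
    """Steiger's test for two dependent correlations sharing one variable.

    Compares corr(j,k) with corr(j,h) given corr(k,h) on the same ``n``
    subjects using Fisher-transformed correlations with the shared-variable
    covariance correction; z = 0 when the two correlations are equal and
    the sign flips when they are swapped.
    """
    if n < 4:
        raise ValidationError("Steiger's test needs n >= 4")
    for r in (r_jk, r_jh, r_kh):
        if abs(r) >= 1:
            raise ValidationError("|r| = 1: Fisher transform diverges")
    z_jk = np.arctanh(r_jk)
    z_jh = np.arctanh(r_jh)
    r_bar = 0.5 * (r_jk + r_jh)
    rb2 = r_bar**2
    cov = (r_kh * (1 - 2 * rb2) - 0.5 * rb2 * (1 - 2 * rb2 - r_kh**2)) / (1 - rb2) ** 2
    z = (z_jk - z_jh) * np.sqrt((n - 3) / (2 * (1 - cov)))
    if one_sided:
        p = float(stats.norm.sf(z))
    else:
        p = float(2 * stats.norm.sf(abs(z)))
    return {"z": float(z), "p": p}


# ---------------------------------------------------------------------------
# experiment harness
# ---------------------------------------------------------------------------


@dataclass
class ExperimentReport:
    method: str
    accuracy: AccuracyTable
    overlap_lesioned: list
    overlap_ground: list
    nmi_table: pd.DataFrame  # subject_id, lesion_size, nmi, lesioned flag
    size_dependence: dict
    nmi_gap: float  # |mean clean NMI - mean lesioned NMI|


def _register_all(subjects, space_img, config, masks=None):
    out = {}
    for i, (sid, img) in enumerate(subjects):
        mask = masks.get(sid) if masks else None
        res = syn_register(space_img, img, lesion_mask=mask, config=config)
        out[sid] = res.transform
    return out


def run_experiment(
    cohort: VirtualCohort,
    method: str = "cohort-template",
    space_image: ImageVolume | None = None,
    registration: RegistrationConfig | None = None,
    template_config: TemplateConfig | None = None,
    nmi_bins: int = 64,
) -> ExperimentReport:
    """Score one normalization arm on a virtual-lesion cohort.

    ``method`` selects the common space: ``"fixed-template"`` registers
    everything to ``space_image`` (an unrelated healthy phantom standing in
    for a population template), ``"cohort-template"`` first builds the
    cohort-specific template from one lesioned image per control.  Every
    subject (clean and lesioned, CCFM for the latter) is registered to the
    space once and the transform reused across pairs; the report holds the
    all-pairs accuracy table against the clean ground truth, per-subject
    NMI vs. the space image, and the lesion-size dependence statistics.
    """
    if registration is None:
        registration = RegistrationConfig()

    clean = {cid: (img, lab) for cid, img, lab in cohort.controls}
    cases = {
        (cid, lid): (img, mask) for cid, lid, img, mask in cohort.cases
    }

    if method == "cohort-template":
        if template_config is None:
            template_config = TemplateConfig(registration=registration)
        # one lesioned image per control with *varied* lesions (diagonal of
        # the controls x lesions cross): each lesion location enters the
        # average with weight 1/n, as in a template built from a lesioned
        # cohort, instead of imprinting one location in every member
        lesion_ids = sorted({lid for _, lid in cases})
        members = [
            cases[(cid, lesion_ids[i % len(lesion_ids)])][0]
            for i, cid in enumerate(sorted(clean))
        ]
        state = build_template(members, config=template_config)
        space_img = state.template
        space_name = "CST"
    elif method == "fixed-template":
        if space_image is None:
            raise ValidationError("fixed-template mode needs a designated space image")
        space_img = space_image
        space_name = "fixed"
    else:
        raise ValidationError(f"unknown method {method!r}")

    # one registration per subject, reused across pairs
    clean_subjects = [(cid, clean[cid][0]) for cid in sorted(clean)]
    case_subjects = [(f"{cid}+{lid}", cases[(cid, lid)][0]) for cid, lid in sorted(cases)]
    case_masks = {f"{cid}+{lid}": cases[(cid, lid)][1] for cid, lid in sorted(cases)}

    t_clean = _register_all(clean_subjects, space_img, registration)
    t_cases = _register_all(case_subjects, space_img, registration, masks=case_masks)

    def labels_of(sid):
        ctl = sid.split("+")[0]
        return clean[ctl][1]

    # all unordered pairs, fixed orientation by sorted id; self-pairs of the
    # clean images serve as ground truth for lesioned pairs that share a
    # control (a round trip through the common space)
    ground_records = []
    for a in sorted(t_clean):
        ground_records.append(
            pairwise_overlap(
                (labels_of(a), t_clean[a]), (labels_of(a), t_clean[a]),
                space=space_name, source_id=a, target_id=a,
            )
        )
    for a, b in itertools.combinations(sorted(t_clean), 2):
        ground_records.append(
            pairwise_overlap(
                (labels_of(a), t_clean[a]), (labels_of(b), t_clean[b]),
                space=space_name, source_id=a, target_id=b,
            )
        )
    lesioned_records = []
    for a, b in itertools.combinations(sorted(t_cases), 2):
        lesioned_records.append(
            pairwise_overlap(
                (labels_of(a), t_cases[a]), (labels_of(b), t_cases[b]),
                space=space_name, source_id=a, target_id=b,
            )
        )
    acc = accuracy_difference(lesioned_records, ground_records, method=method)

    # per-subject NMI vs. the space image within its brain voxels
    brain = otsu_brain_mask(space_img)
    rows = []
    for sid, img in clean_subjects + case_subjects:
        t = t_clean.get(sid) or t_cases.get(sid)
        warped = resample(img, t, space_img.geometry, interpolation="linear")
        lesioned = "+" in sid
        size = case_masks[sid].count() if lesioned else 0
        rows.append(
            {
                "subject_id": sid,
                "lesioned": lesioned,
                "lesion_size_voxels": int(size),
                "nmi": nmi(warped, space_img, bins=nmi_bins, mask=brain),
            }
        )
    nmi_table = pd.DataFrame(rows)

    les = nmi_table[nmi_table.lesioned]
    cln = nmi_table[~nmi_table.lesioned]
    gap = abs(float(cln.nmi.mean()) - float(les.nmi.mean()))
    try:
        dep = size_dependence(les.nmi.to_numpy(), les.lesion_size_voxels.to_numpy())
    except ValidationError:  # too few lesioned subjects / one lesion size
        dep = {"r": float("nan"), "p": float("nan"),
               "slope": float("nan"), "intercept": float("nan")}

    return ExperimentReport(
        method=method,
        accuracy=acc,
        overlap_lesioned=lesioned_records,
        overlap_ground=ground_records,
        nmi_table=nmi_table,
        size_dependence=dep,
        nmi_gap=gap,
    )
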