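"""Domain types and tabular IO for variant activity data and predictor submissions.

The ground truth is a table of missense variants with measured enzymatic
activity expressed as percent of wild type (%WT).  A variant is labeled
pathogenic (class 1) when its activity falls strictly below a cutoff
(default 13 %WT) and benign (class 0) otherwise.  Variants carrying a
definitive ClinVar classification are removed to form the evaluation set;
everything else — including variants of uncertain significance — is retained.

Prediction submissions are separate two-column tables (variant id, raw score)
aligned to the variant table by identifier; scores may be missing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import AlignmentError, FormatError, IntegrityError, ParameterError

DEFAULT_THRESHOLD = 13.0

#: ClinVar significance values regarded as definitive: variants carrying one of
#: these (without a conflicting-interpretations review flag) are excluded from
#: the evaluation set.
DEFINITIVE_SIGNIFICANCE = frozenset(
    {
        "Pathogenic",
        "Likely pathogenic",
        "Pathogenic/Likely pathogenic",
        "Benign",
        "Likely benign",
        "Benign/Likely benign",
    }
)

_CONFLICT_TOKEN = "conflicting interpretations"

#: Tokens treated as missing values when reading tables.
MISSING_TOKENS = frozenset({"", "na", "nan", "."})

CATEGORIES = ("submitted", "public", "feature")

_AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}

_RE_ONE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z])$")
_RE_THREE = re.compile(r"^(?:p\.)?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")


def normalize_variant_id(variant_id: str) -> str:
    """Canonicalize a protein substitution identifier to ``p.X123Y`` form.

    Accepts single-letter (``p.P220L``, ``P220L``) and three-letter
    (``p.Pro220Leu``) HGVS-p dialects without a transcript prefix.
    """
    vid = str(variant_id).strip()
    m = _RE_ONE.match(vid)
    if m:
        return f"p.{m.group(1)}{m.group(2)}{m.group(3)}"
    m = _RE_THREE.match(vid)
    if m:
        ref, pos, alt = m.groups()
        try:
            return f"p.{_AA3_TO_1[ref]}{pos}{_AA3_TO_1[alt]}"
        except KeyError as exc:
            raise FormatError(f"unknown amino-acid code in variant id {vid!r}") from exc
    raise FormatError(f"unparseable variant identifier {vid!r}")


@dataclass(frozen=True)
class VariantRecord:
    """One missense variant: identifier, measured activity and derived label."""

    variant_id: str
    activity: float | None
    clinvar_significance: str | None = None
    clinvar_review: str | None = None
    in_evaluation_set: bool = True
    class_label: int | None = None

    @property
    def has_activity(self) -> bool:
        return self.activity is not None and not np.isnan(self.activity)


@dataclass(frozen=True)
class VariantDataset:
    """An ordered collection of variants sharing one pathogenicity threshold.

    The record order is stable and shared with every aligned
    :class:`PredictionSet`; all array properties follow it.
    """

    records: tuple[VariantRecord, ...]
    threshold: float = DEFAULT_THRESHOLD
    role: str = "curated"  # curated | evaluation

    def __post_init__(self) -> None:
        ids = [r.variant_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({v for v in ids if ids.count(v) > 1})
            raise IntegrityError(f"duplicate variant ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def variant_ids(self) -> tuple[str, ...]:
        return tuple(r.variant_id for r in self.records)

    @property
    def activities(self) -> np.ndarray:
        """Measured %WT activity; NaN where unmeasured."""
        return np.array(
            [r.activity if r.has_activity else np.nan for r in self.records], dtype=float
        )

    @property
    def labels(self) -> np.ndarray:
        """Class labels (1 pathogenic, 0 benign); NaN where undefined."""
        return np.array(
            [np.nan if r.class_label is None else float(r.class_label) for r in self.records],
            dtype=float,
        )

    @property
    def labeled_mask(self) -> np.ndarray:
        return ~np.isnan(self.labels)

    @property
    def evaluation_mask(self) -> np.ndarray:
        """Records that carry a label and belong to the evaluation set."""
        flags = np.array([r.in_evaluation_set for r in self.records], dtype=bool)
        return flags & self.labeled_mask

    def index_of(self) -> dict[str, int]:
        return {r.variant_id: i for i, r in enumerate(self.records)}

    def subset(self, mask: np.ndarray, role: str | None = None) -> "VariantDataset":
        recs = tuple(r for r, keep in zip(self.records, mask) if keep)
        return VariantDataset(recs, threshold=self.threshold, role=role or self.role)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant": self.variant_ids,
                "activity": self.activities,
                "clinvar_significance": [r.clinvar_significance for r in self.records],
                "clinvar_review": [r.clinvar_review for r in self.records],
                "evaluation_set": [int(r.in_evaluation_set) for r in self.records],
                "class_label": self.labels,
            }
        )


@dataclass
class PredictionSet:
    """One predictor's scores, index-aligned with a :class:`VariantDataset`.

    ``raw_scores`` hold the submission as read (NaN = missing); after the
    normalization stage ``normalized_scores`` live on the %WT-activity scale
    and contain no missing values.
    """

    predictor_name: str
    raw_scores: np.ndarray
    team: str = ""
    category: str = "submitted"
    normalized_scores: np.ndarray | None = None
    orientation_flipped: bool | None = None
    transform_used: str | None = None  # direct | flip | minmax | minmax_negated
    orientation_auc: float | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ParameterError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )
        self.raw_scores = np.asarray(self.raw_scores, dtype=float)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.raw_scores).sum())

    @property
    def scores(self) -> np.ndarray:
        """Normalized scores if available, else raw."""
        return self.raw_scores if self.normalized_scores is None else self.normalized_scores


def assign_class_labels(
    dataset: VariantDataset,
    threshold: float | None = None,
    *,
    inclusive: bool = False,
) -> VariantDataset:
    """Derive binary pathogenicity labels from measured activity.

    A variant is pathogenic (label 1) when ``activity < threshold``; with
    ``inclusive=True`` the boundary value itself also counts as pathogenic.
    Records without a measured activity keep an undefined label.
    """
    thr = dataset.threshold if threshold is None else float(threshold)
    records = []
    for r in dataset.records:
        if r.has_activity:
            hit = r.activity <= thr if inclusive else r.activity < thr
            records.append(replace(r, class_label=int(hit)))
        else:
            records.append(replace(r, class_label=None))
    return VariantDataset(tuple(records), threshold=thr, role=dataset.role)


def _is_conflicting(review: str | None) -> bool:
    return review is not None and _CONFLICT_TOKEN in review.lower()


def derive_evaluation_set(curated: VariantDataset) -> VariantDataset:
    """Drop variants with a definitive ClinVar classification.

    A record is removed exactly when its significance (whitespace-trimmed) is
    one of the six definitive categories *and* its review status does not
    mention conflicting interpretations.  Records without ClinVar fields are
    retained; the operation is idempotent.
    """
    kept = []
    for r in curated.records:
        sig = r.clinvar_significance.strip() if r.clinvar_significance else None
        definitive = sig in DEFINITIVE_SIGNIFICANCE and not _is_conflicting(r.clinvar_review)
        if not definitive:
            kept.append(replace(r, in_evaluation_set=True))
    return VariantDataset(tuple(kept), threshold=curated.threshold, role="evaluation")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    try:
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def _parse_float(token: str, *, context: str) -> float:
    tok = token.strip()
    if tok.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(tok)
    except ValueError as exc:
        raise FormatError(f"non-numeric value {token!r} in {context}") from exc


def read_variant_table(
    path: str | Path,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    inclusive: bool = False,
) -> VariantDataset:
    """Read a curated variant table (TSV/CSV by extension; header required).

    Expected columns: ``variant``, ``activity``; optional
    ``clinvar_significance``, ``clinvar_review`` and ``evaluation_set``
    (``evaluationSet`` accepted as alias, values 0/1).  Class labels are
    derived immediately from the threshold.
    """
    df = _read_table(path)
    df = df.rename(columns={"evaluationSet": "evaluation_set"})
    for col in ("variant", "activity"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    has_flag = "evaluation_set" in df.columns

    records = []
    for _, row in df.iterrows():
        vid = normalize_variant_id(row["variant"])
        activity = _parse_float(row["activity"], context=f"activity of {vid}")
        sig = row.get("clinvar_significance", "") or None
        rev = row.get("clinvar_review", "") or None
        if has_flag:
            flag = str(row["evaluation_set"]).strip() in {"1", "true", "True"}
        else:
            flag = not np.isnan(activity)
        if flag and np.isnan(activity):
            raise IntegrityError(
                f"{path}: variant {vid} is flagged for evaluation but has no activity"
            )
        records.append(
            VariantRecord(
                variant_id=vid,
                activity=None if np.isnan(activity) else activity,
                clinvar_significance=sig,
                clinvar_review=rev,
                in_evaluation_set=flag,
            )
        )
    ds = VariantDataset(tuple(records), threshold=threshold, role="curated")
    return assign_class_labels(ds, threshold, inclusive=inclusive)


def write_variant_table(dataset: VariantDataset, path: str | Path) -> None:
    """Write a variant table in the canonical dialect.

    Fixed column order, tab separator, ``.`` decimal, ``NA`` for missing;
    floats use shortest round-trip formatting so write/read is lossless.
    """
    path = Path(path)
    lines = ["variant\tactivity\tclinvar_significance\tclinvar_review\tevaluation_set"]
    for r in dataset.records:
        act = repr(float(r.activity)) if r.has_activity else "NA"
        lines.append(
            "\t".join(
                [
                    r.variant_id,
                    act,
                    r.clinvar_significance or "",
                    r.clinvar_review or "",
                    str(int(r.in_evaluation_set)),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_prediction_table(
    path: str | Path,
    dataset: VariantDataset,
    predictor_name: str,
    team: str = "",
    category: str = "submitted",
) -> PredictionSet:
    """Read a two-column submission (``variant``, ``score``) aligned to *dataset*.

    Variants absent from the file become missing scores; file rows naming
    variants outside the dataset are ignored with a warning.  Raw scores are
    left untouched — normalization is a separate stage.
    """
    df = _read_table(path)
    for col in ("variant", "score"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    index = dataset.index_of()
    scores = np.full(dataset.n, np.nan)
    seen: set[str] = set()
    n_extra = 0
    for _, row in df.iterrows():
        vid = normalize_variant_id(row["variant"])
        if vid in seen:
            raise IntegrityError(f"{path}: duplicate variant {vid}")
        seen.add(vid)
        value = _parse_float(row["score"], context=f"score of {vid}")
        pos = index.get(vid)
        if pos is None:
            n_extra += 1
            continue
        scores[pos] = value
    if not (seen & set(index)):
        raise AlignmentError(f"{path}: no overlap with the variant dataset")
    if n_extra:
        warnings.warn(
            f"{path}: ignored {n_extra} variant(s) not present in the dataset",
            stacklevel=2,
        )
    return PredictionSet(
        predictor_name=predictor_name, raw_scores=scores, team=team, category=category
    )


def write_prediction_table(
    prediction_set: PredictionSet,
    dataset: VariantDataset,
    path: str | Path,
    *,
    which: str = "raw",
) -> None:
    """Write a submission table (``variant``, ``score``) in dataset order."""
    values = (
        prediction_set.raw_scores if which == "raw" else prediction_set.normalized_scores
    )
    if values is None:
        raise IntegrityError("prediction set has no normalized scores to write")
    lines = ["variant\tscore"]
    for vid, v in zip(dataset.variant_ids, values):
        lines.append(f"{vid}\t{'NA' if np.isnan(v) else repr(float(v))}")
    Path(path).write_text("\n".join(lines) + "\n")
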