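"""Cohort-level region-concordance evaluation.

A detection method (visual reading, voxel-wise statistics, or the
subtraction pipeline) assigns each patient a set of cortical regions; the
resection zone (RZ) is the surrogate ground truth.  A patient counts as
concordant for a method when the method's region set intersects the RZ set.

The packaged fixture (``sipcom/data/cohort_tables.csv``) encodes a 20-patient
surgical epilepsy cohort: per-patient SEEG and surgery region sets, MRI
status, Engel outcome class, lobar localisation and the region sets detected
by each method.
"""

from __future__ import annotations

import importlib.resources
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ClusterTable
from .io_prep import Volume3D, check_same_lattice
from .regions import RegionCode, format_region_set, parse_region_set

__all__ = [
    "PatientRecord",
    "load_cohort",
    "patient_concordant",
    "cohort_rates",
    "region_recall_precision",
    "assign_cluster_regions",
    "score_control_fp",
    "METHODS",
    "SUBGROUPS",
    "evaluation_report",
]

#: method-name -> PatientRecord attribute holding its region set
METHODS = {"visual": "visual", "spm": "spm", "sipcom": "sipcom"}

_GOOD_ENGEL = ("1", "2")  # Engel I-II = good outcome


@dataclass(frozen=True)
class PatientRecord:
    """One cohort row: region sets per method plus clinical covariates."""

    patient: int
    engel_class: str
    mri_status: str  # "positive" | "negative"
    lobar_localization: str
    rz: frozenset[RegionCode]  # resection zone (surgery)
    seeg: frozenset[RegionCode]
    visual: frozenset[RegionCode]
    spm: frozenset[RegionCode]
    sipcom: frozenset[RegionCode]
    age: int | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.rz:
            raise ValueError(f"patient {self.patient}: resection zone is empty")
        if self.mri_status not in ("positive", "negative"):
            raise ValueError(f"patient {self.patient}: bad MRI status")
        if not self.engel_class or self.engel_class[0] not in "1234":
            raise ValueError(
                f"patient {self.patient}: cannot parse Engel class "
                f"{self.engel_class!r}"
            )

    @property
    def engel_good(self) -> bool:
        """Engel I-II = good outcome, III-IV = poor."""
        return self.engel_class[0] in _GOOD_ENGEL

    def method_set(self, method: str) -> frozenset[RegionCode]:
        try:
            return getattr(self, METHODS[method])
        except KeyError:
            raise ValueError(
                f"unknown method {method!r}; expected one of {sorted(METHODS)}"
            ) from None


#: named subgroup filters for cohort_rates
SUBGROUPS: dict[str, Callable[[PatientRecord], bool]] = {
    "all": lambda r: True,
    "engel_good": lambda r: r.engel_good,
    "engel_poor": lambda r: not r.engel_good,
    "mri_positive": lambda r: r.mri_status == "positive",
    "mri_negative": lambda r: r.mri_status == "negative",
}


def _fixture_path() -> Path:
    return Path(
        importlib.resources.files("sipcom").joinpath("data/cohort_tables.csv")
    )


def load_cohort(path: str | Path | None = None) -> list[PatientRecord]:
    """Load the cohort table (the packaged fixture when no path is given).

    The ``surgery`` column defines the resection zone; the value ``Idem``
    resolves to the SEEG column.
    """
    df = pd.read_csv(path if path is not None else _fixture_path(), dtype=str)
    records = []
    for _, row in df.iterrows():
        seeg = parse_region_set(row["seeg"])
        surgery_text = row["surgery"].strip()
        rz = seeg if surgery_text.lower() == "idem" else parse_region_set(surgery_text)
        records.append(
            PatientRecord(
                patient=int(row["patient"]),
                age=int(row["age"]) if "age" in row else None,
                engel_class=row["engel_class"].strip(),
                mri_status=row["mri_status"].strip().lower(),
                lobar_localization=row["lobar_localization"].strip(),
                rz=rz,
                seeg=seeg,
                visual=parse_region_set(row["visual"]),
                spm=parse_region_set(row["spm"]),
                sipcom=parse_region_set(row["sipcom"]),
                meta={
                    k: row[k]
                    for k in ("sex", "mri_findings", "pathology", "followup_months")
                    if k in row
                },
            )
        )
    return records


def patient_concordant(record: PatientRecord, method: str) -> bool:
    """True iff the method's region set intersects the resection zone."""
    return bool(record.method_set(method) & record.rz)


def cohort_rates(
    records: Sequence[PatientRecord],
    method: str,
    subgroup: str | Callable[[PatientRecord], bool] | None = None,
) -> tuple[int, int, float]:
    """Patient-level concordance count and rate, optionally in a subgroup.

    Returns
    -------
    (count, n, rate)
        Number concordant, subgroup size, and their exact ratio.
    """
    if subgroup is None:
        pred = SUBGROUPS["all"]
    elif callable(subgroup):
        pred = subgroup
    else:
        try:
            pred = SUBGROUPS[subgroup]
        except KeyError:
            raise ValueError(
                f"unknown subgroup {subgroup!r}; expected one of {sorted(SUBGROUPS)}"
            ) from None
    sub = [r for r in records if pred(r)]
    if not sub:
        raise ValueError("empty subgroup")
    count = sum(patient_concordant(r, method) for r in sub)
    return count, len(sub), count / len(sub)


def region_recall_precision(
    records: Sequence[PatientRecord], method: str
) -> tuple[float, float | None]:
    """Micro-averaged region-level recall and precision.

    recall    = sum_p |method_p ∩ RZ_p| / sum_p |RZ_p|
    precision = sum_p |method_p ∩ RZ_p| / sum_p |method_p|

    This is this package's definition (regions pooled over patients).
    Precision is ``None`` when no method set contains any region.
    """
    hits = sum(len(r.method_set(method) & r.rz) for r in records)
    rz_total = sum(len(r.rz) for r in records)
    det_total = sum(len(r.method_set(method)) for r in records)
    recall = hits / rz_total if rz_total else 0.0
    precision = hits / det_total if det_total else None
    return recall, precision


def assign_cluster_regions(
    table: ClusterTable,
    atlas: Volume3D,
    labels: pd.DataFrame,
    min_fraction: float = 0.0,
) -> ClusterTable:
    """Attach atlas regions (with overlap fractions) to each cluster.

    A region is listed when the fraction of cluster voxels falling in it
    exceeds ``min_fraction`` (default: any overlap).  Clusters with no
    labelled overlap get an empty set.
    """
    check_same_lattice(atlas, table.zmap_like())
    label_to_code = {
        int(row.label_id): RegionCode(f"{row.region_code}_{row.hemisphere}")
        for row in labels.itertuples()
    }
    atlas_data = np.asarray(atlas.data).astype(int)
    for cluster in table.clusters:
        vox = cluster.voxels  # (n, 3) index array
        lab = atlas_data[vox[:, 0], vox[:, 1], vox[:, 2]]
        fractions: dict[RegionCode, float] = {}
        n = len(lab)
        for lid in np.unique(lab):
            if lid == 0:
                continue
            frac = float((lab == lid).sum()) / n
            if frac > min_fraction:
                code = label_to_code.get(int(lid))
                if code is not None:
                    fractions[code] = fractions.get(code, 0.0) + frac
        cluster.regions = frozenset(fractions)
        cluster.region_fractions = fractions
    return table


def score_control_fp(
    tables: Iterable[ClusterTable | int],
) -> dict[str, float]:
    """Summarize false-positive cluster counts over lesion-free subjects.

    Accepts cluster tables or raw per-subject counts.  SD is the sample
    (n-1) form; for a single subject SD is reported as 0 with ``n = 1``.
    """
    counts = [t if isinstance(t, int) else len(t.clusters) for t in tables]
    if not counts:
        raise ValueError("need at least one subject")
    arr = np.asarray(counts, dtype=float)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return {
        "n": len(arr),
        "mean": float(arr.mean()),
        "sd": sd,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


def evaluation_report(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Concordance rates for every method x subgroup, as a tidy table."""
    rows = []
    for method in METHODS:
        for name in SUBGROUPS:
            count, n, rate = cohort_rates(records, method, name)
            rows.append(
                {
                    "method": method,
                    "subgroup": name,
                    "concordant": count,
                    "n": n,
                    "rate_pct": 100.0 * rate,
                }
            )
    return pd.DataFrame(rows)


def format_record(record: PatientRecord) -> str:
    """One-line human-readable summary of a patient row."""
    return (
        f"#{record.patient:>2} Engel {record.engel_class:<2} "
        f"MRI {record.mri_status:<8} RZ [{format_region_set(record.rz)}] "
        f"SIPCOM [{format_region_set(record.sipcom)}]"
    )
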