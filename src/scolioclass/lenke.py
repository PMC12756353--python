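"""Concordance of the index-based classes with the Lenke classification.

Each Lenke curve type maps to the set of vertical-index categories it is
compatible with (types 1-2 thoracic, 3-4 transitional-thoracic, 5 lumbar,
6 transitional-lumbar; a Lenke "Normal" patient is concordant only with an
output of no scoliosis), and each sagittal modifier to a set of
kyphosis-lordosis categories (``+`` hyper-kyphotic, ``N`` normal band,
``-`` hypo-kyphotic with no counterpart category, hence never concordant).
Lordotic outputs (extreme/significant lordosis) have no Lenke counterpart
at all and are pooled into a ``/`` group regardless of the modifier.

Group-wise validated / not-validated counts form a contingency table on
which a Pearson chi-square test of independence and the overall percentage
agreement are computed.  The chi-square statistic is the classic
``sum (O - E)^2 / E`` with ``E`` the product of the margins over the grand
total; df = (rows - 1)(cols - 1); the p-value is the upper tail of the
chi-square distribution.

The observed tables of the 94-patient reference validation cohort ship with
the package (:func:`load_reference_concordance`) so the published agreement
statistics can be recomputed without the restricted clinical data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .classify import Classification, NA
from .errors import ContractError, DegenerateTableError, FormatError, ValidationError
from .io import LenkeRecord, NORMAL_TYPE

__all__ = [
    "ConcordanceTable",
    "ChiSquareResult",
    "PatientValidation",
    "expected_vertical_categories",
    "expected_sagittal_categories",
    "validate_patient",
    "validate_cohort",
    "build_concordance",
    "pearson_chi_square",
    "percent_agreement",
    "read_contingency",
    "write_contingency",
    "load_reference_concordance",
    "concordance_charts",
    "VERTICAL_GROUP_ORDER",
    "SAGITTAL_GROUP_ORDER",
]

VERTICAL_GROUP_ORDER = ("1", "2", "3", "4", "5", "6", "Normal")
SAGITTAL_GROUP_ORDER = ("+", "-", "N", "/")

_EXPECTED_VERTICAL: dict[str, frozenset[str]] = {
    "1": frozenset({"Thoracic", "Mainly thoracic"}),
    "2": frozenset({"Thoracic", "Mainly thoracic"}),
    "3": frozenset({"Mainly thoracic", "Thoraco-lumbar"}),
    "4": frozenset({"Mainly thoracic", "Thoraco-lumbar"}),
    "5": frozenset({"Lumbar", "Mainly lumbar", "Thoraco-lumbar"}),
    "6": frozenset({"Thoraco-lumbar", "Mainly lumbar"}),
    NORMAL_TYPE: frozenset({NA}),
}

_EXPECTED_SAGITTAL: dict[str, frozenset[str]] = {
    "+": frozenset({"Significant kyphosis", "Extreme kyphosis"}),
    "-": frozenset(),
    "N": frozenset({"Normal spine", "Slight kyphosis", "Slight lordosis"}),
}

#: Outputs with no Lenke sagittal counterpart; pooled into the "/" group.
_LORDOSIS_GROUP = frozenset({"Extreme lordosis", "Significant lordosis"})


def expected_vertical_categories(lenke_type: str) -> frozenset[str]:
    """Vertical categories compatible with a Lenke curve type (``"1"``..``"6"``
    or ``"Normal"``, whose only match is a no-scoliosis output)."""
    try:
        return _EXPECTED_VERTICAL[str(lenke_type)]
    except KeyError:
        raise ContractError(f"unknown Lenke curve type {lenke_type!r}") from None


def expected_sagittal_categories(modifier: str) -> frozenset[str]:
    """Sagittal categories compatible with a Lenke sagittal modifier
    (``+``/``-``/``N``; the ``-`` modifier has no counterpart and returns
    the empty set)."""
    mod = str(modifier).replace("−", "-")
    try:
        return _EXPECTED_SAGITTAL[mod]
    except KeyError:
        raise ContractError(f"unknown Lenke sagittal modifier {modifier!r}") from None


@dataclass(frozen=True)
class PatientValidation:
    """Concordance outcome for one patient on both axes."""

    patient_id: str
    v_group: str  # Lenke type row of the vertical table
    v_validated: bool
    kl_group: str  # modifier row (or "/") of the sagittal table
    kl_validated: bool


def validate_patient(cls: Classification, lenke: LenkeRecord) -> PatientValidation:
    """Score one classification against the patient's Lenke record.

    The vertical axis is validated when the vertical category lies in the
    type's compatible set (a Lenke Normal patient validates only a
    no-scoliosis output).  The sagittal axis is validated when the
    kyphosis-lordosis category lies in the modifier's set; lordotic outputs
    go to the ``/`` group and are never validated.  A Lenke Normal patient
    with no modifier is scored against the normal-kyphosis band (``N``).

    Raises
    ------
    ContractError
        If the two records carry different patient ids.
    """
    if cls.patient_id != lenke.patient_id:
        raise ContractError(
            f"patient id mismatch: classification {cls.patient_id!r} vs "
            f"Lenke record {lenke.patient_id!r}"
        )
    v_group = lenke.curve_type
    v_validated = cls.vertical in expected_vertical_categories(lenke.curve_type)

    modifier = lenke.sagittal_modifier if lenke.sagittal_modifier is not None else "N"
    if cls.sagittal in _LORDOSIS_GROUP:
        kl_group, kl_validated = "/", False
    else:
        kl_group = modifier.replace("−", "-")
        kl_validated = cls.sagittal in expected_sagittal_categories(modifier)
    return PatientValidation(
        patient_id=cls.patient_id,
        v_group=v_group,
        v_validated=v_validated,
        kl_group=kl_group,
        kl_validated=kl_validated,
    )


@dataclass(frozen=True)
class ConcordanceTable:
    """Group x {validated, not validated} counts."""

    rows: tuple[str, ...]
    validated: tuple[int, ...]
    not_validated: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.rows) == len(self.validated) == len(self.not_validated)):
            raise ValidationError("rows and count columns must have equal length")
        if any(v < 0 for v in self.validated + self.not_validated):
            raise ValidationError("counts must be non-negative")
        if self.grand_total <= 0:
            raise ValidationError("grand total must be positive")

    @property
    def counts(self) -> np.ndarray:
        """(r, 2) observed counts, columns [validated, not_validated]."""
        return np.column_stack([self.validated, self.not_validated]).astype(float)

    @property
    def grand_total(self) -> int:
        return int(sum(self.validated) + sum(self.not_validated))

    def expected(self) -> np.ndarray:
        """Expected counts under independence (margins product / total)."""
        O = self.counts
        return np.outer(O.sum(axis=1), O.sum(axis=0)) / O.sum()


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def build_concordance(
    records: Iterable[tuple[str, bool]],
    row_order: Optional[Sequence[str]] = None,
) -> ConcordanceTable:
    """Aggregate ``(group, validated)`` pairs into a contingency table.

    ``row_order`` fixes the row labels (groups absent from the data get
    zero rows); without it, rows appear in first-seen order.
    """
    records = list(records)
    if not records and row_order is None:
        raise ContractError("no records to aggregate")
    counts: dict[str, list[int]] = {}
    order: list[str] = list(row_order) if row_order is not None else []
    for g in order:
        counts[g] = [0, 0]
    for group, ok in records:
        if group not in counts:
            if row_order is not None:
                raise ValidationError(f"group {group!r} not in the fixed row order")
            order.append(group)
            counts[group] = [0, 0]
        counts[group][0 if ok else 1] += 1
    return ConcordanceTable(
        rows=tuple(order),
        validated=tuple(counts[g][0] for g in order),
        not_validated=tuple(counts[g][1] for g in order),
    )


def validate_cohort(
    classifications: Iterable[Classification],
    lenke_records: Iterable[LenkeRecord],
) -> list[PatientValidation]:
    """Join classifications with Lenke records by patient id and score each.

    Patients present on only one side are ignored (callers may warn)."""
    by_id = {r.patient_id: r for r in lenke_records}
    out = []
    for cls in classifications:
        rec = by_id.get(cls.patient_id)
        if rec is not None:
            out.append(validate_patient(cls, rec))
    return out


def pearson_chi_square(table: ConcordanceTable) -> ChiSquareResult:
    """Pearson chi-square test of independence on the contingency table.

    Raises
    ------
    DegenerateTableError
        If any row or column total is zero (an expected count would be 0).
    """
    O = table.counts
    row_tot = O.sum(axis=1)
    col_tot = O.sum(axis=0)
    if np.any(row_tot == 0) or np.any(col_tot == 0):
        raise DegenerateTableError("zero row or column total; expected count undefined")
    E = np.outer(row_tot, col_tot) / O.sum()
    statistic = float(((O - E) ** 2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return ChiSquareResult(
        statistic=statistic, df=df, p_value=float(stats.chi2.sf(statistic, df))
    )


def percent_agreement(table: ConcordanceTable) -> float:
    """Overall percentage agreement: 100 x validated / grand total."""
    return 100.0 * sum(table.validated) / table.grand_total


# -- contingency CSV ------------------------------------------------------


def read_contingency(path: Union[str, Path]) -> ConcordanceTable:
    """Read a ``group,validated,not_validated`` CSV (header optional)."""
    path = Path(path)
    rows: list[str] = []
    val: list[int] = []
    nval: list[int] = []
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or all(not c.strip() for c in row):
                continue
            if lineno == 1 and row[0].strip().lower() == "group":
                continue
            if len(row) < 3:
                raise FormatError(f"{path}:{lineno}: expected group,validated,not_validated")
            try:
                v, n = int(row[1]), int(row[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: counts must be integers") from None
            rows.append(row[0].strip())
            val.append(v)
            nval.append(n)
    if not rows:
        raise FormatError(f"{path}: no contingency rows")
    return ConcordanceTable(rows=tuple(rows), validated=tuple(val), not_validated=tuple(nval))


def write_contingency(table: ConcordanceTable, path: Union[str, Path]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["group", "validated", "not_validated"])
        for g, v, n in zip(table.rows, table.validated, table.not_validated):
            w.writerow([g, v, n])


def load_reference_concordance(axis: str) -> ConcordanceTable:
    """Observed concordance counts of the 94-patient reference validation
    cohort, bundled with the package.

    ``axis`` is ``"vertical"`` (Lenke curve types 1-6 + Normal versus
    vertical-index categories) or ``"sagittal"`` (sagittal modifiers +/-/N
    plus the ``/`` lordosis group versus kyphosis-lordosis categories).
    """
    names = {"vertical": "lenke_vindex_concordance.csv", "sagittal": "lenke_sagittal_concordance.csv"}
    if axis not in names:
        raise ContractError(f"axis must be 'vertical' or 'sagittal', got {axis!r}")
    ref = resources.files("scolioclass.data") / names[axis]
    with resources.as_file(ref) as p:
        return read_contingency(p)


# -- charts ----------------------------------------------------------------


def concordance_charts(
    table: ConcordanceTable, out_dir: Union[str, Path], prefix: str = "concordance"
) -> list[Path]:
    """Write a stacked bar chart of observed counts and a heat map of the
    expected frequencies under independence; returns the file paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    groups = list(table.rows)
    v = np.array(table.validated)
    n = np.array(table.not_validated)

    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.bar(groups, v, label="validated", color="#2a9d8f")
    ax.bar(groups, n, bottom=v, label="not validated", color="#e76f51")
    ax.set_xlabel("group")
    ax.set_ylabel("patients")
    ax.set_title("Observed concordance by group")
    ax.legend()
    bar_path = out_dir / f"{prefix}_stacked_bar.png"
    fig.tight_layout()
    fig.savefig(bar_path, dpi=150)
    plt.close(fig)

    E = table.expected()
    fig, ax = plt.subplots(figsize=(5, 0.8 + 0.6 * len(groups)))
    im = ax.imshow(E, cmap="viridis", aspect="auto")
    ax.set_xticks([0, 1], labels=["validated", "not validated"])
    ax.set_yticks(range(len(groups)), labels=groups)
    for i in range(E.shape[0]):
        for j in range(E.shape[1]):
            ax.text(j, i, f"{E[i, j]:.1f}", ha="center", va="center", color="w")
    fig.colorbar(im, ax=ax, label="expected count")
    ax.set_title("Expected frequencies under independence")
    heat_path = out_dir / f"{prefix}_expected_heatmap.png"
    fig.tight_layout()
    fig.savefig(heat_path, dpi=150)
    plt.close(fig)
    return [bar_path, heat_path]
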