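"""CYP51A1 missense/nonsense variant records: classification, filtering, QC.

Variant effect predictions come in as printed SIFT and PolyPhen-2 scores and
labels (the predictors themselves are never run here).  Threshold classes are
recomputed from the scores with the tools' standard conventions:

* SIFT: score <= 0.05 -> damaging, else tolerated.
* PolyPhen-2 (HumDiv bins): score >= 0.957 -> probably damaging,
  >= 0.453 -> possibly damaging, else benign.

Printed labels are stored verbatim and never overwritten — the source tables
contain internally inconsistent labels (a 0.93 printed "Benign" next to a
0.930 printed "Probably damaging"), so :func:`consistency_check` reports
label/class disagreements instead of silently resolving them.

Residue numbering follows the NP_000777.1 reference protein.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "VariantRecord",
    "ClassLabel",
    "MismatchReport",
    "classify_sift",
    "classify_polyphen",
    "load_variant_table",
    "load_packaged_table",
    "packaged_table_path",
    "filter_damaging_both",
    "count_by_region",
    "consistency_check",
    "SIFT_DAMAGING_MAX",
    "POLYPHEN_PROBABLY_MIN",
    "POLYPHEN_POSSIBLY_MIN",
]

SIFT_DAMAGING_MAX = 0.05
POLYPHEN_PROBABLY_MIN = 0.957
POLYPHEN_POSSIBLY_MIN = 0.453

# <ref aa><position><alt aa | * | Ter | del...>
_PROTEIN_CHANGE_RE = re.compile(r"^([A-Z])(\d+)(Ter|del[A-Za-z]*|\*|[A-Z])$")


class VariantParseError(ValueError):
    """A variant table row could not be parsed."""


def classify_sift(score: float) -> str:
    """SIFT threshold class: ``damaging`` iff score <= 0.05, else ``tolerated``."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"SIFT score must lie in [0, 1], got {score}")
    return "damaging" if score <= SIFT_DAMAGING_MAX else "tolerated"


def classify_polyphen(score: float) -> str:
    """PolyPhen-2 threshold class under the HumDiv bin edges."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"PolyPhen-2 score must lie in [0, 1], got {score}")
    if score >= POLYPHEN_PROBABLY_MIN:
        return "probably_damaging"
    if score >= POLYPHEN_POSSIBLY_MIN:
        return "possibly_damaging"
    return "benign"


@dataclass(frozen=True)
class ClassLabel:
    sift_class: str  # damaging | tolerated | unknown
    polyphen_class: str  # probably_damaging | possibly_damaging | benign | unknown

    def __post_init__(self) -> None:
        if self.sift_class not in ("damaging", "tolerated", "unknown"):
            raise ValueError(f"bad sift_class {self.sift_class!r}")
        if self.polyphen_class not in (
            "probably_damaging", "possibly_damaging", "benign", "unknown",
        ):
            raise ValueError(f"bad polyphen_class {self.polyphen_class!r}")


@dataclass(frozen=True)
class VariantRecord:
    """One protein-level variant with printed predictor output.

    ``sift_label_printed`` / ``polyphen_label_printed`` preserve the source
    table verbatim; ``classes`` holds the recomputed threshold classes
    (``unknown`` where a score is absent, e.g. termination and deletion
    variants).
    """

    snp_id: str
    protein_change: str
    sift_score: float | None
    sift_label_printed: str | None
    polyphen_score: float | None
    polyphen_label_printed: str | None
    region: str
    note: str = ""

    def __post_init__(self) -> None:
        if not _PROTEIN_CHANGE_RE.match(self.protein_change):
            raise VariantParseError(
                f"malformed protein change {self.protein_change!r}"
            )
        for score, tool in ((self.sift_score, "SIFT"), (self.polyphen_score, "PolyPhen-2")):
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValueError(f"{tool} score out of [0, 1]: {score}")

    @property
    def ref_aa(self) -> str:
        return _PROTEIN_CHANGE_RE.match(self.protein_change).group(1)

    @property
    def position(self) -> int:
        return int(_PROTEIN_CHANGE_RE.match(self.protein_change).group(2))

    @property
    def alt(self) -> str:
        return _PROTEIN_CHANGE_RE.match(self.protein_change).group(3)

    @property
    def is_termination(self) -> bool:
        return self.alt in ("*", "Ter")

    @property
    def is_deletion(self) -> bool:
        return self.alt.startswith("del")

    @property
    def classes(self) -> ClassLabel:
        sift = "unknown" if self.sift_score is None else classify_sift(self.sift_score)
        poly = (
            "unknown" if self.polyphen_score is None else classify_polyphen(self.polyphen_score)
        )
        return ClassLabel(sift_class=sift, polyphen_class=poly)


def _absent(cell: object) -> bool:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return True
    s = str(cell).strip()
    return s in ("", "/", "nan")


def load_variant_table(path: str | Path) -> list[VariantRecord]:
    """Load a TSV variant table (header required) into records.

    Cells that are blank or "/" map to absent values.  A malformed protein
    change raises :class:`VariantParseError` carrying the 1-based data row
    number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"snp_id", "protein_change", "region"}
    missing = required - set(df.columns)
    if missing:
        raise VariantParseError(f"{path}: missing column(s) {sorted(missing)}")
    records: list[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        get = lambda col: getattr(row, col, None) if col in df.columns else None
        try:
            records.append(
                VariantRecord(
                    snp_id="/" if _absent(get("snp_id")) else str(get("snp_id")).strip(),
                    protein_change=str(get("protein_change")).strip(),
                    sift_score=None if _absent(get("sift_score")) else float(get("sift_score")),
                    sift_label_printed=None if _absent(get("sift_label")) else str(get("sift_label")).strip(),
                    polyphen_score=None if _absent(get("polyphen_score")) else float(get("polyphen_score")),
                    polyphen_label_printed=None if _absent(get("polyphen_label")) else str(get("polyphen_label")).strip(),
                    region="" if _absent(get("region")) else str(get("region")).strip(),
                    note="" if _absent(get("note")) else str(get("note")).strip(),
                )
            )
        except (VariantParseError, ValueError) as exc:
            raise VariantParseError(f"{path}: data row {i}: {exc}") from exc
    return records


def packaged_table_path(name: str) -> Path:
    """Path of a packaged fixture table, e.g. ``table4_conserved_regions``."""
    fname = name if name.endswith(".tsv") else f"{name}.tsv"
    return Path(resources.files("cyp51var").joinpath("data", fname))


def load_packaged_table(name: str) -> list[VariantRecord]:
    return load_variant_table(packaged_table_path(name))


def filter_damaging_both(records: list[VariantRecord]) -> list[VariantRecord]:
    """Records classed damaging by SIFT and (probably or possibly) damaging
    by PolyPhen-2; records lacking either score are excluded."""
    out = []
    for r in records:
        if r.sift_score is None or r.polyphen_score is None:
            continue
        c = r.classes
        if c.sift_class == "damaging" and c.polyphen_class in (
            "probably_damaging", "possibly_damaging",
        ):
            out.append(r)
    return out


def count_by_region(records: list[VariantRecord]) -> dict[str, int]:
    """Multiset count of the region annotation (empty regions skipped)."""
    counts: dict[str, int] = {}
    for r in records:
        if r.region:
            counts[r.region] = counts.get(r.region, 0) + 1
    return counts


_LABEL_NORMALISATION = {
    "damaging": "damaging",
    "deleterious": "damaging",
    "tolerated": "tolerated",
    "probably damaging": "probably_damaging",
    "possibly damaging": "possibly_damaging",
    "benign": "benign",
}


@dataclass(frozen=True)
class MismatchReport:
    snp_id: str
    protein_change: str
    tool: str
    score: float
    printed_label: str
    computed_class: str


def consistency_check(records: list[VariantRecord]) -> list[MismatchReport]:
    """QC: flag records whose printed label disagrees with the threshold
    class recomputed from the printed score.  Records with absent scores or
    unrecognised labels produce no report."""
    reports: list[MismatchReport] = []
    for r in records:
        pairs = [
            ("SIFT", r.sift_score, r.sift_label_printed, classify_sift),
            ("PolyPhen-2", r.polyphen_score, r.polyphen_label_printed, classify_polyphen),
        ]
        for tool, score, label, classify in pairs:
            if score is None or label is None:
                continue
            normalised = _LABEL_NORMALISATION.get(label.strip().lower())
            if normalised is None:
                continue
            computed = classify(score)
            if computed != normalised:
                reports.append(
                    MismatchReport(
                        snp_id=r.snp_id,
                        protein_change=r.protein_change,
                        tool=tool,
                        score=score,
                        printed_label=label,
                        computed_class=computed,
                    )
                )
    return reports
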