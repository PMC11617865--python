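"""Reading FreeSurfer-style stats tables and assembling validated cohorts.

The expected table layout is the one produced by ``aparcstats2table`` /
``asegstats2table``: one header row of column labels, first column the
subject id, remaining columns numeric regional measurements. Summary columns
(eTIV, BrainSegVol and friends) are recognised and split off as covariate
candidates rather than treated as network nodes. Both tab- and general
whitespace-delimited files are accepted.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlases import AtlasSpec
from .exceptions import ConsistencyError, TableParseError, ValidationError

#: Column names (case-insensitive regex) treated as whole-brain summary
#: measures, never as ROI nodes.
SUMMARY_COLUMN_PATTERNS = (
    r"^etiv$",
    r"^estimatedtotalintracranialvol(ume)?$",
    r"^icv$",
    r"^intracranialvol(ume)?$",
    r"^brainsegvol.*$",
    r"^(lh|rh)?[._]?(meanthickness|whitesurfarea|corticalwhitemattervol).*$",
    r"^(mask|supratentorial|subcort|cerebral|cortex|totalgray).*vol.*$",
    r"^surfaceholes$",
)
_SUMMARY_RE = re.compile("|".join(SUMMARY_COLUMN_PATTERNS), re.IGNORECASE)


def is_summary_column(label: str) -> bool:
    """True if ``label`` names a whole-brain summary column, not an ROI."""
    core = re.sub(r"_(thickness|volume|area|mean)$", "", label, flags=re.IGNORECASE)
    return bool(_SUMMARY_RE.match(label) or _SUMMARY_RE.match(core))


@dataclass
class ROITable:
    """A subjects x ROIs block of one morphometric measure.

    ``values`` is ``float64`` with subjects in row order of the source file;
    thickness is in mm, volume in mm^3. ``covariate_candidates`` carries any
    summary columns (e.g. eTIV) found alongside the ROI columns.
    """

    subject_ids: list[str]
    roi_names: list[str]
    values: np.ndarray
    measure_kind: str  # "thickness" | "volume"
    covariate_candidates: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.measure_kind not in ("thickness", "volume"):
            raise ValidationError(f"measure_kind must be thickness|volume, got {self.measure_kind!r}")
        if self.values.shape != (len(self.subject_ids), len(self.roi_names)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.roi_names)} ROIs"
            )
        if self.values.size == 0:
            raise ValidationError("empty ROI table")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value for subject {self.subject_ids[bad[0]]!r}, "
                f"ROI {self.roi_names[bad[1]]!r}"
            )
        if self.measure_kind == "thickness" and np.any(self.values <= 0):
            bad = np.argwhere(self.values <= 0)[0]
            raise ValidationError(
                f"non-positive thickness for subject {self.subject_ids[bad[0]]!r}, "
                f"ROI {self.roi_names[bad[1]]!r}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subject_ids, columns=self.roi_names)


def read_stats_table(path: str | Path, measure_kind: str) -> ROITable:
    """Read an ``aparcstats2table``-style TSV into an :class:`ROITable`.

    Summary columns are split into ``covariate_candidates``. Non-numeric
    cells raise :class:`TableParseError` naming the row and column.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"stats table not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
        if df.shape[1] == 1:  # not actually tab-delimited; retry on whitespace
            df = pd.read_csv(path, sep=r"\s+", dtype=str)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty stats table: {path}") from None
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise ValidationError(f"stats table {path} has no data rows or no ROI columns")
    subject_ids = df.iloc[:, 0].astype(str).tolist()
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns[1:]:
        converted = pd.to_numeric(df[col], errors="coerce")
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna())[0])
            raise TableParseError(
                f"non-numeric value {df[col].iloc[row]!r} in {path.name}, "
                f"row {row + 2} (subject {subject_ids[row]!r}), column {col!r}"
            )
        numeric[col] = converted.astype(float)
    roi_cols = [c for c in numeric.columns if not is_summary_column(c)]
    cov_cols = [c for c in numeric.columns if is_summary_column(c)]
    if not roi_cols:
        raise ValidationError(f"stats table {path} contains only summary columns")
    covariates = numeric[cov_cols].copy()
    covariates.index = pd.Index(subject_ids, name="subject_id")
    return ROITable(
        subject_ids=subject_ids,
        roi_names=roi_cols,
        values=numeric[roi_cols].to_numpy(),
        measure_kind=measure_kind,
        covariate_candidates=covariates,
    )


def write_stats_table(table: ROITable, path: str | Path) -> None:
    """Write a table back in the same TSV layout (round-trips with the reader)."""
    df = table.to_frame()
    df.index.name = "subject_id"
    for col in table.covariate_candidates.columns:
        df[col] = table.covariate_candidates[col].to_numpy()
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_covariate_table(path: str | Path) -> pd.DataFrame:
    """Read the covariate TSV (subject_id, group, age, icv[, pair_id, session])."""
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"covariate table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "group": str, "pair_id": str})
    if df.shape[1] == 1:
        df = pd.read_csv(path, sep=r"\s+", dtype={"subject_id": str, "group": str, "pair_id": str})
    required = {"subject_id", "group", "age"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"covariate table {path} missing columns: {sorted(missing)}")
    return df


@dataclass
class Cohort:
    """Subjects x ROI measurements bound to covariates and an atlas.

    One row per subject; ROI columns are in atlas order. ``pair_id`` is
    present only for longitudinal (paired) designs and must then map every
    subject to exactly one two-member pair.
    """

    subject_ids: list[str]
    values: np.ndarray  # subjects x atlas.n_nodes, float64
    group_labels: np.ndarray  # str per subject
    age: np.ndarray  # years
    icv: np.ndarray  # mm^3
    atlas: AtlasSpec
    measure_kind: str = "volume"
    pair_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        self.values = np.asarray(self.values, dtype=float)
        self.group_labels = np.asarray(self.group_labels, dtype=object)
        self.age = np.asarray(self.age, dtype=float)
        self.icv = np.asarray(self.icv, dtype=float)
        if len(set(self.subject_ids)) != n:
            raise ValidationError("duplicate subject ids in cohort")
        if self.values.shape != (n, self.atlas.n_nodes):
            raise ValidationError(
                f"ROI matrix shape {self.values.shape} != "
                f"({n} subjects, {self.atlas.n_nodes} atlas nodes)"
            )
        for name, arr in (("group_labels", self.group_labels), ("age", self.age), ("icv", self.icv)):
            if len(arr) != n:
                raise ValidationError(f"{name} length {len(arr)} != {n} subjects")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite ROI values in cohort")
        if not (np.all(np.isfinite(self.age)) and np.all(np.isfinite(self.icv))):
            raise ValidationError("non-finite covariates in cohort")
        if self.pair_id is not None:
            self.pair_id = np.asarray(self.pair_id, dtype=object)
            if len(self.pair_id) != n:
                raise ValidationError("pair_id length mismatch")
            counts = pd.Series(self.pair_id).value_counts()
            bad = counts[counts != 2]
            if len(bad):
                raise ValidationError(
                    f"pair_id must map each subject to a 2-member pair; offending pairs: "
                    f"{sorted(bad.index.tolist())}"
                )

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group_labels:
            seen.setdefault(str(g))
        return list(seen)

    def group_indices(self, label: str) -> np.ndarray:
        idx = np.flatnonzero(self.group_labels == label)
        if idx.size == 0:
            raise KeyError(f"group label {label!r} not present; have {self.groups}")
        return idx

    def subset(self, index: Sequence[int], group_labels: np.ndarray | None = None) -> "Cohort":
        """Row subset (optionally with reassigned labels); used by permutation.

        ``pair_id`` is carried over only when every selected pair remains
        complete (a single-scan subset of a longitudinal cohort is unpaired).
        """
        index = np.asarray(index, dtype=int)
        pair = None
        if self.pair_id is not None:
            sub_pairs = self.pair_id[index]
            counts = pd.Series(sub_pairs).value_counts()
            if len(counts) and (counts == 2).all():
                pair = sub_pairs
        return Cohort(
            subject_ids=[self.subject_ids[i] for i in index],
            values=self.values[index],
            group_labels=(self.group_labels[index] if group_labels is None else group_labels),
            age=self.age[index],
            icv=self.icv[index],
            atlas=self.atlas,
            measure_kind=self.measure_kind,
            pair_id=pair,
        )

    def covariate_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "subject_id": self.subject_ids,
                "group": self.group_labels,
                "age": self.age,
                "icv": self.icv,
            }
        )
        if self.pair_id is not None:
            df["pair_id"] = self.pair_id
        return df


def concat_cohorts(a: Cohort, b: Cohort) -> Cohort:
    """Stack two cohorts over the same atlas (disjoint subject ids required)."""
    if a.atlas.roi_names != b.atlas.roi_names:
        raise ConsistencyError("cohorts use different atlases")
    overlap = set(a.subject_ids) & set(b.subject_ids)
    if overlap:
        raise ConsistencyError(f"overlapping subject ids: {sorted(overlap)[:5]}")
    pair = None
    if a.pair_id is not None and b.pair_id is not None:
        pair = np.concatenate([a.pair_id, b.pair_id])
    return Cohort(
        subject_ids=a.subject_ids + b.subject_ids,
        values=np.vstack([a.values, b.values]),
        group_labels=np.concatenate([a.group_labels, b.group_labels]),
        age=np.concatenate([a.age, b.age]),
        icv=np.concatenate([a.icv, b.icv]),
        atlas=a.atlas,
        measure_kind=a.measure_kind,
        pair_id=pair,
    )


def assemble_cohort(
    tables: ROITable | Iterable[ROITable],
    covariates: pd.DataFrame,
    atlas: AtlasSpec,
) -> Cohort:
    """Join one or more ROI tables with a covariate table into a Cohort.

    ROI columns from all tables must jointly cover ``atlas.roi_names``; they
    are reordered to atlas order. Subjects follow the covariate-table order.
    ICV is taken from the ``icv`` covariate column, falling back to an eTIV
    summary column found in any of the tables.
    """
    if isinstance(tables, ROITable):
        tables = [tables]
    tables = list(tables)
    if not tables:
        raise ValidationError("no ROI tables given")
    kinds = {t.measure_kind for t in tables}

    # Tables may split the ROI columns over a common subject set (lh + rh
    # aparc files) or split the subjects over a common ROI set (per-group
    # files); first column-join within subject-set groups, then row-concat.
    by_subjects: dict[frozenset, pd.DataFrame] = {}
    for t in tables:
        key = frozenset(t.subject_ids)
        if key in by_subjects:
            dup = set(by_subjects[key].columns) & set(t.roi_names)
            if dup:
                raise ConsistencyError(
                    f"ROI label appears in more than one table: {sorted(dup)[:5]}"
                )
            by_subjects[key] = by_subjects[key].join(t.to_frame(), how="inner")
        else:
            by_subjects[key] = t.to_frame()
    blocks = list(by_subjects.values())
    seen: set[str] = set()
    for key in by_subjects:
        overlap = seen & set(key)
        if overlap:
            raise ConsistencyError(
                f"subject appears in tables with different subject sets: "
                f"{sorted(overlap)[:5]}"
            )
        seen |= set(key)
    if len(blocks) > 1:
        cols = set(blocks[0].columns)
        if any(set(b.columns) != cols for b in blocks[1:]):
            raise ConsistencyError(
                "tables with disjoint subject sets must share identical ROI columns"
            )
        merged = pd.concat([b[blocks[0].columns.tolist()] for b in blocks])
    else:
        merged = blocks[0]

    cov = covariates.copy()
    if "subject_id" not in cov.columns:
        raise ValidationError("covariate table lacks a subject_id column")
    cov["subject_id"] = cov["subject_id"].astype(str)
    table_ids = set(merged.index)
    cov_ids = set(cov["subject_id"])
    missing_in_cov = sorted(table_ids - cov_ids)
    missing_in_tab = sorted(cov_ids - table_ids)
    if missing_in_cov or missing_in_tab:
        raise ConsistencyError(
            f"subject id mismatch: in tables but not covariates {missing_in_cov[:10]}; "
            f"in covariates but not tables {missing_in_tab[:10]}"
        )

    uncovered = [r for r in atlas.roi_names if r not in merged.columns]
    if uncovered:
        raise ConsistencyError(
            f"atlas ROIs absent from all tables ({len(uncovered)}): {uncovered[:10]}"
        )
    extra = [c for c in merged.columns if c not in set(atlas.roi_names)]
    if extra:
        warnings.warn(f"ignoring {len(extra)} table columns not in atlas: {extra[:5]}")
    merged = merged.loc[cov["subject_id"].tolist(), list(atlas.roi_names)]

    if "icv" in cov.columns and cov["icv"].notna().all():
        icv = pd.to_numeric(cov["icv"]).to_numpy(dtype=float)
    else:
        pieces = []
        for t in tables:
            for c in t.covariate_candidates.columns:
                if re.match(r"^(etiv|estimatedtotalintracranialvol(ume)?|icv)$", c, re.IGNORECASE):
                    pieces.append(t.covariate_candidates[c])
                    break
        etiv = pd.concat(pieces) if pieces else None
        if etiv is not None and not set(cov["subject_id"]) <= set(etiv.index):
            etiv = None
        if etiv is None:
            raise ValidationError(
                "no 'icv' covariate column and no eTIV column found in any table"
            )
        icv = etiv.loc[cov["subject_id"].tolist()].to_numpy(dtype=float)

    return Cohort(
        subject_ids=cov["subject_id"].tolist(),
        values=merged.to_numpy(),
        group_labels=cov["group"].to_numpy(dtype=object),
        age=pd.to_numeric(cov["age"]).to_numpy(dtype=float),
        icv=icv,
        atlas=atlas,
        measure_kind="thickness" if kinds == {"thickness"} else "volume",
        pair_id=cov["pair_id"].to_numpy(dtype=object) if "pair_id" in cov.columns else None,
    )
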