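"""Reading, writing and validation of 3D landmark data.

Landmark configurations are stored as dense arrays of shape
``(n_specimens, p_landmarks, 3)`` together with specimen metadata
(group membership in ``{"wild", "domestic"}``, pair identity) and two
sidecar structures: a module map assigning each landmark to the neural
crest (NC) or mesoderm (MD) module, and a bilateral symmetry pairing
(left/right landmark index pairs plus midline landmarks).

Files use 1-based landmark numbers; all in-memory indices are 0-based.
Specimens with any missing coordinate are rejected rather than imputed.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

VALID_GROUPS = ("wild", "domestic")
VALID_MODULES = ("NC", "MD")


class LandmarkError(ValueError):
    """Raised for malformed or inconsistent landmark data."""


@dataclass
class LandmarkDataset:
    """Specimens x landmarks x 3 coordinates with group labels.

    Parameters
    ----------
    coords
        Array ``(n, p, 3)`` of raw coordinates in a consistent length unit.
    specimen_ids
        Opaque specimen identifiers, one per row of ``coords``.
    group
        Per-specimen label, each ``"wild"`` or ``"domestic"``.
    pair_id
        Identifier of the domestic/wild pair (e.g. ``"pig_wildboar"``).
    landmark_names
        Optional landmark names; defaults to ``LM1 .. LMp``.
    """

    coords: np.ndarray
    specimen_ids: list[str]
    group: list[str]
    pair_id: str = "pair"
    landmark_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise LandmarkError(
                f"coords must have shape (n, p, 3), got {self.coords.shape}"
            )
        n, p, _ = self.coords.shape
        if len(self.specimen_ids) != n:
            raise LandmarkError("specimen_ids length does not match coords")
        if len(self.group) != n:
            raise LandmarkError("group length does not match coords")
        bad = [g for g in self.group if g not in VALID_GROUPS]
        if bad:
            raise LandmarkError(
                f"invalid group labels {sorted(set(bad))}; valid: {VALID_GROUPS}"
            )
        if not self.landmark_names:
            self.landmark_names = [f"LM{i + 1}" for i in range(p)]
        if len(self.landmark_names) != p:
            raise LandmarkError("landmark_names length does not match coords")
        bad_ij = np.argwhere(~np.isfinite(self.coords))
        if bad_ij.size:
            i, j, _ = bad_ij[0]
            raise LandmarkError(
                f"non-finite coordinate for specimen '{self.specimen_ids[i]}' "
                f"landmark {self.landmark_names[j]}"
            )

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def subset_specimens(self, idx: Sequence[int]) -> "LandmarkDataset":
        idx = list(idx)
        return LandmarkDataset(
            coords=self.coords[idx],
            specimen_ids=[self.specimen_ids[i] for i in idx],
            group=[self.group[i] for i in idx],
            pair_id=self.pair_id,
            landmark_names=list(self.landmark_names),
        )


@dataclass
class ModuleMap:
    """Per-landmark assignment to the NC or MD module."""

    assignment: list[str]

    def __post_init__(self) -> None:
        bad = [a for a in self.assignment if a not in VALID_MODULES]
        if bad:
            raise LandmarkError(
                f"invalid module labels {sorted(set(bad))}; valid: {VALID_MODULES}"
            )
        if not self.indices("NC") or not self.indices("MD"):
            raise LandmarkError("both NC and MD modules must be non-empty")

    @property
    def n_nc(self) -> int:
        return len(self.indices("NC"))

    @property
    def n_md(self) -> int:
        return len(self.indices("MD"))

    def indices(self, which: str) -> list[int]:
        if which not in VALID_MODULES:
            raise LandmarkError(f"unknown module '{which}'; valid: {VALID_MODULES}")
        return [i for i, a in enumerate(self.assignment) if a == which]

    def as_labels(self) -> np.ndarray:
        return np.asarray(self.assignment)


@dataclass
class SymmetryPairing:
    """Bilateral landmark pairing: (left, right) index pairs plus midline."""

    pairs: list[tuple[int, int]]
    midline: list[int]

    def validate(self, p: int) -> None:
        seen: set[int] = set()
        for left, right in self.pairs:
            for k in (left, right):
                if not 0 <= k < p:
                    raise LandmarkError(f"pairing index {k} out of range (p={p})")
                if k in seen:
                    raise LandmarkError(f"landmark index {k} appears more than once")
                seen.add(k)
        for k in self.midline:
            if not 0 <= k < p:
                raise LandmarkError(f"midline index {k} out of range (p={p})")
            if k in seen:
                raise LandmarkError(f"landmark index {k} appears more than once")
            seen.add(k)
        if len(seen) != p:
            missing = sorted(set(range(p)) - seen)
            raise LandmarkError(f"pairing does not cover landmarks {missing}")


# ---------------------------------------------------------------------------
# readers / writers


def read_landmarks(path: str | Path, dialect: str, pair_id: str = "pair") -> LandmarkDataset:
    """Read a landmark file in the named dialect.

    Dialects: ``csv-wide`` (one row per specimen, columns ``LMi_x`` etc.),
    ``csv-long`` (columns specimen, group, landmark, x, y, z) and ``tps``
    (``LM3=`` blocks, read-only).  Row and landmark order are preserved.
    """
    path = Path(path)
    if not path.exists():
        raise LandmarkError(f"no such file: {path}")
    if dialect == "csv-wide":
        return _read_csv_wide(path, pair_id)
    if dialect == "csv-long":
        return _read_csv_long(path, pair_id)
    if dialect == "tps":
        return _read_tps(path, pair_id)
    raise LandmarkError(
        f"unknown dialect '{dialect}'; valid: csv-wide, csv-long, tps"
    )


def _parse_coord(raw: str, specimen: str, landmark: str) -> float:
    try:
        value = float(raw)
    except (TypeError, ValueError):
        value = np.nan
    if not np.isfinite(value):
        raise LandmarkError(
            f"missing or non-numeric coordinate for specimen '{specimen}' "
            f"landmark {landmark}"
        )
    return value


def _read_csv_wide(path: Path, pair_id: str) -> LandmarkDataset:
    df = pd.read_csv(path, dtype=str)
    if "specimen" not in df.columns or "group" not in df.columns:
        raise LandmarkError("csv-wide requires 'specimen' and 'group' columns")
    lm_cols = [c for c in df.columns if re.fullmatch(r"LM\d+_[xyz]", c)]
    numbers = sorted({int(c.split("_")[0][2:]) for c in lm_cols})
    if not numbers:
        raise LandmarkError("no LMi_x/y/z columns found")
    coords = np.empty((len(df), len(numbers), 3))
    for row_i, row in df.iterrows():
        for j, num in enumerate(numbers):
            for k, ax in enumerate("xyz"):
                col = f"LM{num}_{ax}"
                if col not in df.columns:
                    raise LandmarkError(f"missing column {col}")
                coords[row_i, j, k] = _parse_coord(
                    row[col], str(row["specimen"]), f"LM{num}"
                )
    return LandmarkDataset(
        coords=coords,
        specimen_ids=[str(s) for s in df["specimen"]],
        group=[str(g) for g in df["group"]],
        pair_id=pair_id,
        landmark_names=[f"LM{num}" for num in numbers],
    )


def _read_csv_long(path: Path, pair_id: str) -> LandmarkDataset:
    df = pd.read_csv(path, dtype=str)
    required = {"specimen", "group", "landmark", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise LandmarkError(f"csv-long requires columns {sorted(required)}")
    spec_order = list(dict.fromkeys(df["specimen"]))
    lm_order = list(dict.fromkeys(df["landmark"].astype(int)))
    p = len(lm_order)
    coords = np.full((len(spec_order), p, 3), np.nan)
    groups: dict[str, str] = {}
    lm_pos = {lm: j for j, lm in enumerate(lm_order)}
    spec_pos = {s: i for i, s in enumerate(spec_order)}
    for _, row in df.iterrows():
        i = spec_pos[row["specimen"]]
        j = lm_pos[int(row["landmark"])]
        groups[row["specimen"]] = row["group"]
        for k, ax in enumerate("xyz"):
            coords[i, j, k] = _parse_coord(row[ax], row["specimen"], f"LM{lm_order[j]}")
    nan_rows = np.argwhere(np.isnan(coords))
    if nan_rows.size:
        i, j, _ = nan_rows[0]
        raise LandmarkError(
            f"specimen '{spec_order[i]}' is missing landmark LM{lm_order[j]}"
        )
    return LandmarkDataset(
        coords=coords,
        specimen_ids=spec_order,
        group=[groups[s] for s in spec_order],
        pair_id=pair_id,
        landmark_names=[f"LM{lm}" for lm in lm_order],
    )


def _read_tps(path: Path, pair_id: str) -> LandmarkDataset:
    configs: list[np.ndarray] = []
    ids: list[str] = []
    groups: list[str] = []
    current: list[list[float]] = []
    expected = 0
    current_id = ""
    current_group = "wild"

    def flush() -> None:
        nonlocal current, expected, current_id, current_group
        if expected == 0:
            return
        if len(current) != expected:
            raise LandmarkError(
                f"specimen '{current_id or len(configs)}' has {len(current)} "
                f"landmarks, expected {expected}"
            )
        configs.append(np.array(current))
        ids.append(current_id or f"spec{len(configs)}")
        groups.append(current_group)
        current, expected, current_id, current_group = [], 0, "", "wild"

    for raw_line in path.read_text().splitlines():
        line = raw_line.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("LM3=") or upper.startswith("LM="):
            flush()
            expected = int(line.split("=", 1)[1])
        elif upper.startswith("ID="):
            current_id = line.split("=", 1)[1].strip()
        elif upper.startswith("GROUP="):
            current_group = line.split("=", 1)[1].strip()
        elif "=" in line and not line[0].isdigit() and not line[0] in "+-.":
            continue  # other TPS keywords (IMAGE=, SCALE=, ...) ignored
        else:
            parts = line.split()
            if len(parts) != 3:
                raise LandmarkError(
                    f"expected 3 coordinates per line, got {len(parts)}: '{line}'"
                )
            current.append([_parse_coord(v, current_id, f"LM{len(current)+1}") for v in parts])
    flush()
    if not configs:
        raise LandmarkError(f"no landmark records found in {path}")
    ps = {c.shape[0] for c in configs}
    if len(ps) != 1:
        raise LandmarkError(f"inconsistent landmark counts across specimens: {sorted(ps)}")
    return LandmarkDataset(
        coords=np.stack(configs), specimen_ids=ids, group=groups, pair_id=pair_id
    )


def write_landmarks(dataset: LandmarkDataset, path: str | Path, dialect: str) -> None:
    """Write a dataset as csv-wide or csv-long (full float precision)."""
    path = Path(path)
    if dialect == "csv-wide":
        cols: dict[str, list] = {"specimen": dataset.specimen_ids, "group": dataset.group}
        for j in range(dataset.n_landmarks):
            for k, ax in enumerate("xyz"):
                cols[f"LM{j + 1}_{ax}"] = [
                    repr(float(v)) for v in dataset.coords[:, j, k]
                ]
        pd.DataFrame(cols).to_csv(path, index=False)
    elif dialect == "csv-long":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["specimen", "group", "landmark", "x", "y", "z"])
            for i, sid in enumerate(dataset.specimen_ids):
                for j in range(dataset.n_landmarks):
                    x, y, z = dataset.coords[i, j]
                    writer.writerow(
                        [sid, dataset.group[i], j + 1, repr(float(x)), repr(float(y)), repr(float(z))]
                    )
    else:
        raise LandmarkError(f"unknown write dialect '{dialect}'; valid: csv-wide, csv-long")


def read_module_map(path: str | Path, dataset: LandmarkDataset) -> ModuleMap:
    """Read a two-column CSV (landmark, module) aligned to the dataset.

    Landmark numbers in the file are 1-based and must cover every landmark
    of ``dataset`` exactly once with labels in {NC, MD}.
    """
    df = pd.read_csv(path, dtype=str)
    if not {"landmark", "module"}.issubset(df.columns):
        raise LandmarkError("module map requires columns 'landmark' and 'module'")
    p = dataset.n_landmarks
    assignment: list[str | None] = [None] * p
    for _, row in df.iterrows():
        num = int(row["landmark"])
        if not 1 <= num <= p:
            raise LandmarkError(f"module map landmark {num} out of range 1..{p}")
        if assignment[num - 1] is not None:
            raise LandmarkError(f"module map assigns landmark {num} more than once")
        label = str(row["module"]).strip()
        if label not in VALID_MODULES:
            raise LandmarkError(
                f"invalid module label '{label}' for landmark {num}; valid: {VALID_MODULES}"
            )
        assignment[num - 1] = label
    missing = [i + 1 for i, a in enumerate(assignment) if a is None]
    if missing:
        raise LandmarkError(f"module map missing landmarks {missing}")
    return ModuleMap(assignment=list(assignment))  # type: ignore[arg-type]


def write_module_map(module_map: ModuleMap, path: str | Path) -> None:
    pd.DataFrame(
        {"landmark": range(1, len(module_map.assignment) + 1), "module": module_map.assignment}
    ).to_csv(path, index=False)


def read_symmetry_pairing(path: str | Path, dataset: LandmarkDataset) -> SymmetryPairing:
    """Read a two-column CSV (left, right) of 1-based landmark numbers.

    Rows with an empty ``right`` field declare midline landmarks.
    """
    df = pd.read_csv(path, dtype=str)
    if not {"left", "right"}.issubset(df.columns):
        raise LandmarkError("symmetry pairing requires columns 'left' and 'right'")
    pairs: list[tuple[int, int]] = []
    midline: list[int] = []
    for _, row in df.iterrows():
        left = int(row["left"])
        right = row["right"]
        if pd.isna(right) or str(right).strip() == "":
            midline.append(left - 1)
        else:
            pairs.append((left - 1, int(right) - 1))
    pairing = SymmetryPairing(pairs=pairs, midline=midline)
    pairing.validate(dataset.n_landmarks)
    return pairing


def write_symmetry_pairing(pairing: SymmetryPairing, path: str | Path) -> None:
    rows = [{"left": l + 1, "right": r + 1} for l, r in pairing.pairs]
    rows += [{"left": m + 1, "right": ""} for m in pairing.midline]
    pd.DataFrame(rows, columns=["left", "right"]).to_csv(path, index=False)


def split_pair(dataset: LandmarkDataset) -> tuple[LandmarkDataset, LandmarkDataset]:
    """Split a pair dataset into its (wild, domestic) subsets."""
    wild_idx = [i for i, g in enumerate(dataset.group) if g == "wild"]
    dom_idx = [i for i, g in enumerate(dataset.group) if g == "domestic"]
    if not wild_idx or not dom_idx:
        raise LandmarkError(
            f"both groups required, found only {sorted(set(dataset.group))}"
        )
    return dataset.subset_specimens(wild_idx), dataset.subset_specimens(dom_idx)
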