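"""List-mode data ingestion and artefact serialization.

Multi-sample flow cytometry data arrives as one list-mode file per
individual (FCS 3.0/3.1 or a per-sample CSV matrix of cells x markers)
plus a manifest assigning each file an individual id and a group label.
Everything downstream operates on :class:`MFCDataset`, a stacked
cells-x-markers matrix with per-cell individual membership and
per-individual group labels — the multiset structure in which cells are
nested within individuals nested within groups.

No compensation or spillover handling is applied at ingestion: files are
read as acquired.
"""

from __future__ import annotations

import json
import warnings
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MFCDataset",
    "SampleManifest",
    "MarkerResolutionError",
    "PanelMismatchError",
    "ManifestError",
    "read_fcs_sample",
    "write_fcs_sample",
    "read_csv_sample",
    "assemble_dataset",
    "save_archive",
    "load_archive",
]


class MarkerResolutionError(KeyError):
    """A requested marker name does not exist in a file's panel."""


class PanelMismatchError(ValueError):
    """Samples do not share a common marker panel."""


class ManifestError(ValueError):
    """The sample manifest is malformed (e.g. duplicate individual ids)."""


# ---------------------------------------------------------------------------
# Canonical dataset container
# ---------------------------------------------------------------------------


@dataclass
class MFCDataset:
    """Stacked multiset of single-cell measurements.

    Attributes
    ----------
    values : ndarray, shape (total_cells, J)
        Marker intensities in arbitrary fluorescence units (or any
        monotone transform thereof once preprocessed).
    cell_to_individual : ndarray of int, shape (total_cells,)
        Index into ``individual_ids`` for every cell.
    individual_ids : list of str
        Unique sample identifiers, one per individual.
    group_labels : ndarray of int, shape (I,)
        Group index ``g`` in ``{1..G}`` per individual; ``g=1`` is the
        control group by convention, ``g=2`` the challenged group.
    marker_names : list of str
        The J marker (parameter) names shared by all individuals.
    group_names : list of str
        Original group labels, ``group_names[g-1]`` maps back from the
        integer coding.
    """

    values: np.ndarray
    cell_to_individual: np.ndarray
    individual_ids: list[str]
    group_labels: np.ndarray
    marker_names: list[str]
    group_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.cell_to_individual = np.asarray(self.cell_to_individual, dtype=np.intp)
        self.group_labels = np.asarray(self.group_labels, dtype=np.intp)
        if not self.group_names:
            self.group_names = [str(g) for g in sorted(set(self.group_labels.tolist()))]
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D cells x markers matrix")
        n, j = self.values.shape
        if len(self.marker_names) != j:
            raise ValueError("marker_names length does not match values columns")
        if self.cell_to_individual.shape != (n,):
            raise ValueError("cell_to_individual must have one entry per cell")
        I = len(self.individual_ids)
        if len(set(self.individual_ids)) != I:
            raise ManifestError("individual_ids must be unique")
        if self.group_labels.shape != (I,):
            raise ValueError("group_labels must have one entry per individual")
        if n and (self.cell_to_individual.min() < 0 or self.cell_to_individual.max() >= I):
            raise ValueError("cell_to_individual refers to a nonexistent individual")
        counts = np.bincount(self.cell_to_individual, minlength=I)
        if I and counts.min() < 1:
            empty = self.individual_ids[int(np.argmin(counts))]
            raise ValueError(f"individual {empty!r} has no cells")

    # -- derived quantities -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_groups(self) -> int:
        return int(np.max(self.group_labels)) if self.n_individuals else 0

    @property
    def cell_counts(self) -> np.ndarray:
        """N_ig: number of cells per individual."""
        return np.bincount(self.cell_to_individual, minlength=self.n_individuals)

    def cells_of(self, individual: int) -> np.ndarray:
        """Rows of ``values`` belonging to one individual (view-safe copy)."""
        return self.values[self.cell_to_individual == individual]

    def with_values(self, values: np.ndarray) -> "MFCDataset":
        """New dataset sharing all structure but with replaced values."""
        return MFCDataset(
            values=np.asarray(values, dtype=np.float64),
            cell_to_individual=self.cell_to_individual.copy(),
            individual_ids=list(self.individual_ids),
            group_labels=self.group_labels.copy(),
            marker_names=list(self.marker_names),
            group_names=list(self.group_names),
        )

    def subset(self, individuals: Sequence[int]) -> "MFCDataset":
        """Dataset restricted to the given individual indices (in that order).

        Used by cross-validation to build leakage-free training sets:
        every fitted statistic downstream sees only these individuals.
        """
        individuals = list(individuals)
        keep_rows = []
        new_index = np.empty(self.n_cells, dtype=np.intp)
        for new_i, old_i in enumerate(individuals):
            rows = np.nonzero(self.cell_to_individual == old_i)[0]
            keep_rows.append(rows)
            new_index[rows] = new_i
        rows = np.concatenate(keep_rows) if keep_rows else np.empty(0, dtype=np.intp)
        return MFCDataset(
            values=self.values[rows],
            cell_to_individual=new_index[rows],
            individual_ids=[self.individual_ids[i] for i in individuals],
            group_labels=self.group_labels[individuals],
            marker_names=list(self.marker_names),
            group_names=list(self.group_names),
        )


@dataclass
class SampleManifest:
    """Rows of (file_path, individual_id, group_label).

    The manifest, not the file contents, defines sample identity: the
    same file listed twice under different ids yields two individuals.
    Group integer coding follows first appearance order in the manifest
    (first-seen label -> g=1).
    """

    files: list[str]
    individual_ids: list[str]
    group_labels: list[str]

    def __post_init__(self) -> None:
        if not (len(self.files) == len(self.individual_ids) == len(self.group_labels)):
            raise ManifestError("manifest columns must have equal length")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            dupes = {i for i in self.individual_ids if self.individual_ids.count(i) > 1}
            raise ManifestError(f"duplicate individual ids in manifest: {sorted(dupes)}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleManifest":
        df = pd.read_csv(path, dtype=str)
        required = {"file", "individual", "group"}
        if not required.issubset(df.columns):
            raise ManifestError(f"manifest must have columns {sorted(required)}")
        return cls(
            files=df["file"].tolist(),
            individual_ids=df["individual"].tolist(),
            group_labels=df["group"].tolist(),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"file": self.files, "individual": self.individual_ids, "group": self.group_labels}
        ).to_csv(path, index=False)

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.group_labels:
            if g not in seen:
                seen.append(g)
        return seen


# ---------------------------------------------------------------------------
# FCS 3.0 / 3.1 list-mode reader and writer
# ---------------------------------------------------------------------------

_DELIM_SENTINEL = "\x00DELIM\x00"


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    delim = raw[:1].decode("latin-1")
    body = raw.decode("latin-1")
    # Escaped delimiters appear doubled inside values.
    body = body[1:]
    if body.endswith(delim):
        body = body[:-1]
    parts = body.replace(delim + delim, _DELIM_SENTINEL).split(delim)
    parts = [p.replace(_DELIM_SENTINEL, delim) for p in parts]
    if len(parts) % 2:
        parts = parts[:-1]
    return {k.strip().upper(): v for k, v in zip(parts[::2], parts[1::2])}


def read_fcs_sample(
    path: str | Path, marker_subset: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Read one FCS 3.0/3.1 list-mode file.

    Returns the (N x J') event matrix in acquisition order together with
    the parameter names used, with no compensation and no transformation
    applied. ``marker_subset`` selects and orders columns by $PnN name.

    Supports $DATATYPE F (float32), D (float64) and I (unsigned
    integer, byte-aligned widths), both byte orders, $MODE L.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        header = fh.read(58)
        if len(header) < 58 or not header[:3] == b"FCS":
            raise OSError(f"{path}: not an FCS file")
        version = header[:6].decode("latin-1")
        if version not in ("FCS3.0", "FCS3.1"):
            warnings.warn(f"{path}: FCS version {version!r}, parsing as 3.x")

        def _off(a: int, b: int) -> int:
            txt = header[a:b].decode("latin-1").strip()
            return int(txt) if txt else 0

        text_start, text_end = _off(10, 18), _off(18, 26)
        data_start, data_end = _off(26, 34), _off(34, 42)
        fh.seek(text_start)
        text = _parse_text_segment(fh.read(text_end - text_start + 1))

        if data_start == 0 or data_end == 0:
            data_start = int(text.get("$BEGINDATA", "0"))
            data_end = int(text.get("$ENDDATA", "0"))
        n_par = int(text["$PAR"])
        n_tot = int(text["$TOT"])
        datatype = text.get("$DATATYPE", "F").upper()
        mode = text.get("$MODE", "L").upper()
        if mode != "L":
            raise OSError(f"{path}: only list mode ($MODE L) is supported, got {mode}")
        byteord = text.get("$BYTEORD", "1,2,3,4")
        little = byteord.startswith("1")
        order = "<" if little else ">"

        names = [
            text.get(f"$P{i}N", text.get(f"$P{i}S", f"P{i}")) for i in range(1, n_par + 1)
        ]
        bits = [int(text.get(f"$P{i}B", "32")) for i in range(1, n_par + 1)]

        fh.seek(data_start)
        raw = fh.read(data_end - data_start + 1)

    if datatype == "F":
        data = np.frombuffer(raw[: 4 * n_par * n_tot], dtype=f"{order}f4")
    elif datatype == "D":
        data = np.frombuffer(raw[: 8 * n_par * n_tot], dtype=f"{order}f8")
    elif datatype == "I":
        widths = {b // 8 for b in bits}
        if len(widths) != 1 or bits[0] % 8:
            raise OSError(f"{path}: mixed or non-byte-aligned integer widths unsupported")
        w = bits[0] // 8
        dt = {1: "u1", 2: "u2", 4: "u4", 8: "u8"}[w]
        data = np.frombuffer(raw[: w * n_par * n_tot], dtype=f"{order}{dt}")
    else:
        raise OSError(f"{path}: unsupported $DATATYPE {datatype}")

    matrix = np.asarray(data, dtype=np.float64).reshape(n_tot, n_par)

    if marker_subset is not None:
        idx = []
        for name in marker_subset:
            if name not in names:
                raise MarkerResolutionError(
                    f"marker {name!r} not in {path.name}; available: {names}"
                )
            idx.append(names.index(name))
        matrix = matrix[:, idx]
        names = list(marker_subset)
    return matrix, names


def write_fcs_sample(
    path: str | Path, values: np.ndarray, marker_names: Sequence[str]
) -> None:
    """Write an (N x J) event matrix as a minimal FCS 3.1 file.

    Data are stored as little-endian float32 in list mode; used to
    produce fixtures and to export simulated cohorts.
    """
    values = np.asarray(values, dtype=np.float32)
    n_tot, n_par = values.shape
    if len(marker_names) != n_par:
        raise ValueError("marker_names length must equal number of columns")

    payload = values.astype("<f4").tobytes()
    delim = "/"
    kv = {
        "$BEGINANALYSIS": "0",
        "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0",
        "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4",
        "$DATATYPE": "F",
        "$MODE": "L",
        "$NEXTDATA": "0",
        "$PAR": str(n_par),
        "$TOT": str(n_tot),
    }
    for i, name in enumerate(marker_names, start=1):
        kv[f"$P{i}N"] = str(name).replace(delim, "_")
        kv[f"$P{i}B"] = "32"
        kv[f"$P{i}E"] = "0,0"
        kv[f"$P{i}R"] = str(int(max(1.0, float(np.max(values)) if values.size else 1.0)) + 1)

    header_len = 58
    # Two-pass layout: TEXT length depends on the offsets it encodes.
    data_start = data_end = 0
    for _ in range(3):
        kv["$BEGINDATA"] = str(data_start)
        kv["$ENDDATA"] = str(data_end)
        text = delim + delim.join(f"{k}{delim}{v}" for k, v in sorted(kv.items())) + delim
        text_start = header_len
        text_end = text_start + len(text) - 1
        new_start = text_end + 1
        new_end = new_start + len(payload) - 1
        if (new_start, new_end) == (data_start, data_end):
            break
        data_start, data_end = new_start, new_end

    def _fmt(x: int) -> bytes:
        s = str(x)
        if len(s) > 8:
            s = "0"  # too large for the header; TEXT keywords carry it
        return s.rjust(8).encode("ascii")

    header = b"FCS3.1    " + _fmt(text_start) + _fmt(text_end) + _fmt(data_start) + _fmt(data_end) + _fmt(0) + _fmt(0)
    assert len(header) == 58
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text.encode("latin-1"))
        fh.write(payload)


def read_csv_sample(
    path: str | Path, marker_subset: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Read a per-sample CSV matrix (header of marker names, one row per cell)."""
    df = pd.read_csv(path)
    names = [str(c) for c in df.columns]
    if marker_subset is not None:
        for name in marker_subset:
            if name not in names:
                raise MarkerResolutionError(
                    f"marker {name!r} not in {Path(path).name}; available: {names}"
                )
        df = df[list(marker_subset)]
        names = list(marker_subset)
    return df.to_numpy(dtype=np.float64), names


def _read_sample(path: str | Path, marker_subset=None):
    if str(path).lower().endswith(".fcs"):
        return read_fcs_sample(path, marker_subset)
    return read_csv_sample(path, marker_subset)


def assemble_dataset(
    manifest: SampleManifest, marker_subset: Sequence[str] | None = None
) -> MFCDataset:
    """Stack per-individual files into one :class:`MFCDataset`.

    Cells are stacked in manifest order; all files must share the marker
    panel (after optional ``marker_subset`` selection).
    """
    blocks: list[np.ndarray] = []
    panel: list[str] | None = None
    for f in manifest.files:
        matrix, names = _read_sample(f, marker_subset)
        if panel is None:
            panel = names
        elif names != panel:
            raise PanelMismatchError(
                f"marker panel of {f} ({names}) differs from first file ({panel})"
            )
        if matrix.shape[0] == 0:
            raise ValueError(f"file {f} contains no cells")
        blocks.append(matrix)

    group_names = manifest.group_names
    group_of = {name: g + 1 for g, name in enumerate(group_names)}
    counts = [b.shape[0] for b in blocks]
    return MFCDataset(
        values=np.vstack(blocks),
        cell_to_individual=np.repeat(np.arange(len(blocks)), counts),
        individual_ids=list(manifest.individual_ids),
        group_labels=np.array([group_of[g] for g in manifest.group_labels]),
        marker_names=list(panel or []),
        group_names=group_names,
    )


# ---------------------------------------------------------------------------
# Model archive: one self-describing zip of JSON metadata + npy arrays
# ---------------------------------------------------------------------------

ARCHIVE_FORMAT_VERSION = 1


def save_archive(path: str | Path, meta: dict, arrays: dict[str, np.ndarray]) -> None:
    """Serialize a fitted model: JSON metadata plus named arrays in a zip."""
    meta = dict(meta)
    meta["archive_format_version"] = ARCHIVE_FORMAT_VERSION
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("meta.json", json.dumps(meta, indent=2))
        for name, arr in arrays.items():
            import io as _io

            buf = _io.BytesIO()
            np.save(buf, np.asarray(arr), allow_pickle=False)
            zf.writestr(f"arrays/{name}.npy", buf.getvalue())


def load_archive(path: str | Path) -> tuple[dict, dict[str, np.ndarray]]:
    with zipfile.ZipFile(path, "r") as zf:
        meta = json.loads(zf.read("meta.json"))
        arrays = {}
        for info in zf.infolist():
            if info.filename.startswith("arrays/") and info.filename.endswith(".npy"):
                import io as _io

                arrays[info.filename[len("arrays/") : -4]] = np.load(
                    _io.BytesIO(zf.read(info.filename)), allow_pickle=False
                )
    return meta, arrays
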