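"""Reading and writing the tabular and sparse formats used by the pipeline.

Coordinates, responses, proportions and dense expression matrices travel as
delimited text (TSV or CSV, chosen by file extension); sparse expression can
be Matrix Market triplets with plain-text row/column name sidecars.  All
loaders align rows by spot identifier (never by file order) and impose a
deterministic sorted-id row order, so permuting the rows of any input file
never changes the loaded dataset.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .dataset import AlignmentError, RunConfig, SpatialDataset, ValidationError
from .model import CoefficientField


class FilterError(ValidationError):
    """Raised when a filter removes every predictor."""


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_table(path: Path, index_col: int = 0) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=index_col)
    df.index = df.index.map(str)
    return df


def _read_matrix(path: Path, orientation: str) -> pd.DataFrame:
    """Dense delimited or Matrix Market (+ .rows.txt/.cols.txt sidecars) matrix.

    Returns a spots x features frame regardless of on-disk orientation.
    """
    path = Path(path)
    if path.suffix.lower() == ".mtx":
        mat = scipy.io.mmread(str(path))
        if sp.issparse(mat):
            mat = mat.toarray()
        rows = Path(str(path) + ".rows.txt").read_text().split()
        cols = Path(str(path) + ".cols.txt").read_text().split()
        if mat.shape != (len(rows), len(cols)):
            raise ValidationError(
                f"matrix shape {mat.shape} does not match sidecar names "
                f"({len(rows)}, {len(cols)})"
            )
        df = pd.DataFrame(np.asarray(mat, dtype=float), index=rows, columns=cols)
    else:
        df = _read_table(path)
        bad = df.map(lambda v: isinstance(v, str)).to_numpy()
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-numeric cell at row {df.index[i]!r}, column {df.columns[j]!r} "
                f"in {path.name}"
            )
        df = df.astype(float)
    if orientation == "genes_by_spots":
        df = df.T
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    return df


def read_spatial_dataset(
    coords_path: str | Path,
    response_path: str | Path,
    predictors_path: str | Path,
    options: RunConfig | None = None,
    section_id: str | None = None,
) -> SpatialDataset:
    """Load one section from three files, aligning all rows by spot id.

    ``coords_path`` holds columns ``(id, x, y)``; ``response_path`` holds
    ``(id, value)``; ``predictors_path`` is a dense spots-by-features table
    (or features-by-spots with ``options.orientation='genes_by_spots'``) or a
    Matrix Market file with name sidecars.  Spot ids must coincide across the
    three files; mismatches raise :class:`AlignmentError` naming offenders.
    """
    options = options or RunConfig()
    coords_path = Path(coords_path)
    coords = _read_table(coords_path)
    if coords.shape[1] < 2:
        raise ValidationError("coordinates file needs id, x, y columns")
    coords = coords.iloc[:, :2].astype(float)
    response = _read_table(Path(response_path)).iloc[:, 0].astype(float)
    predictors = _read_matrix(Path(predictors_path), options.orientation)

    for name, index in (
        ("coordinates", coords.index),
        ("response", response.index),
        ("predictors", predictors.index),
    ):
        if index.duplicated().any():
            dupes = sorted(index[index.duplicated()].unique())
            raise ValidationError(f"duplicate spot ids in {name}: {dupes[:5]}")

    ids = [set(coords.index), set(response.index), set(predictors.index)]
    common = ids[0] & ids[1] & ids[2]
    union = ids[0] | ids[1] | ids[2]
    if common != union:
        missing = sorted(union - common)
        raise AlignmentError(
            f"spot ids not shared by all inputs: {missing[:10]}"
            + (" ..." if len(missing) > 10 else "")
        )

    order = sorted(common)
    dataset = SpatialDataset(
        spot_ids=order,
        coords=coords.loc[order].to_numpy(),
        response=response.loc[order].to_numpy(),
        predictors=predictors.loc[order].to_numpy(),
        predictor_names=list(predictors.columns),
        section_id=section_id or coords_path.stem,
    )
    if options.log_normalize:
        dataset.predictors = np.log1p(dataset.predictors)
        dataset.response = np.log1p(dataset.response)
    return dataset


def filter_low_prevalence(
    predictors: np.ndarray,
    names: list[str],
    min_fraction: float = 0.10,
) -> tuple[np.ndarray, list[str]]:
    """Drop features observed (nonzero) in fewer than ``min_fraction`` of spots.

    The boundary is inclusive: a feature nonzero in exactly ``min_fraction``
    of spots is retained; only strictly-lower prevalence is removed.  Column
    order of survivors is preserved, and the operation is idempotent.
    """
    if not 0.0 <= min_fraction <= 1.0:
        raise ValidationError("min_fraction must be in [0, 1]")
    predictors = np.atleast_2d(np.asarray(predictors, dtype=float))
    n = predictors.shape[0]
    prevalence = (predictors != 0).sum(axis=0) / n
    keep = prevalence >= min_fraction
    if not keep.any():
        raise FilterError("no predictors survive the prevalence filter")
    kept_names = [name for name, k in zip(names, keep) if k]
    return predictors[:, keep], kept_names


def apply_prevalence_filter(dataset: SpatialDataset, min_fraction: float = 0.10) -> SpatialDataset:
    """Dataset-level wrapper around :func:`filter_low_prevalence`."""
    filtered, names = filter_low_prevalence(
        dataset.predictors, dataset.predictor_names, min_fraction
    )
    cols = [dataset.predictor_names.index(name) for name in names]
    return dataset.subset_predictors(cols)


_FLOAT_FMT = "%.17g"  # >= 12 significant digits for lossless text round-trips


def write_coefficient_field(
    field: CoefficientField, path: str | Path, layout: str = "long"
) -> None:
    """Serialize a coefficient field as delimited text.

    ``long`` layout emits ``(spot_id, predictor, coefficient)`` rows, one per
    nonzero entry (an all-zero field yields a header-only file); ``dense``
    emits the full n x p table.  Both round-trip through
    :func:`read_coefficient_field` to < 1e-10 absolute error.
    """
    path = Path(path)
    sep = _sep_for(path)
    if layout == "dense":
        df = pd.DataFrame(field.values, index=field.spot_ids, columns=field.predictor_names)
        df.index.name = "spot_id"
        df.to_csv(path, sep=sep, float_format=_FLOAT_FMT)
    elif layout == "long":
        ii, jj = np.nonzero(field.values)
        df = pd.DataFrame(
            {
                "spot_id": [field.spot_ids[i] for i in ii],
                "predictor": [field.predictor_names[j] for j in jj],
                "coefficient": field.values[ii, jj],
            }
        )
        df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    else:
        raise ValidationError(f"unknown layout {layout!r}")


def read_coefficient_field(
    path: str | Path,
    layout: str = "long",
    spot_ids: list[str] | None = None,
    predictor_names: list[str] | None = None,
) -> CoefficientField:
    """Inverse of :func:`write_coefficient_field`.

    The long layout omits zeros, so reconstructing the full field needs the
    spot/predictor universes; if not given they are inferred from the rows
    present (spots or predictors that are zero everywhere are then absent).
    """
    path = Path(path)
    sep = _sep_for(path)
    if layout == "dense":
        df = pd.read_csv(path, sep=sep, index_col=0)
        return CoefficientField(
            df.to_numpy(dtype=float),
            [str(s) for s in df.index],
            [str(c) for c in df.columns],
        )
    if layout != "long":
        raise ValidationError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep=sep, dtype={"spot_id": str, "predictor": str})
    spots = spot_ids or sorted(df["spot_id"].unique())
    preds = predictor_names or sorted(df["predictor"].unique())
    values = np.zeros((len(spots), len(preds)))
    si = {s: i for i, s in enumerate(spots)}
    pi = {g: j for j, g in enumerate(preds)}
    for _, row in df.iterrows():
        values[si[row["spot_id"]], pi[row["predictor"]]] = row["coefficient"]
    return CoefficientField(values, list(spots), list(preds))


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(
    path: str | Path, config: dict, seed: int, inputs: dict[str, str | Path]
) -> None:
    """Emit a YAML run manifest: config, seed and input checksums."""
    manifest = {
        "config": config,
        "seed": int(seed),
        "inputs": {
            name: {"path": str(p), "sha256": file_checksum(p)}
            for name, p in inputs.items()
        },
    }
    Path(path).write_text(yaml.safe_dump(manifest, sort_keys=True))
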