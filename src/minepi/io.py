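"""Delimited genotype-phenotype tables and prediction writers.

The file boundary uses genotype strings, never integer indices.  Tables
are UTF-8 delimited text (tab or comma, sniffed when not specified) with
a header row and columns ``genotype``, ``phenotype`` and optionally
``variance``.  Writers emit a JSON sidecar recording the space
definition, settings and seeds so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .interpolation import InterpolationResult, ObservationSet
from .spaces import GenotypeSpace, make_space


def _package_version() -> str:
    try:
        return version("minepi")
    except PackageNotFoundError:
        return "unknown"


def read_observations(
    path: str | Path,
    alphabet: Sequence[str] | str,
    l: int,
    sep: str | None = None,
    on_duplicate: str = "error",
    genotype_cap: int | None = None,
) -> ObservationSet:
    """Read a genotype-phenotype table into an ObservationSet.

    ``on_duplicate`` is 'error' (reject duplicated genotypes, naming the
    first offender) or 'mean' (average duplicate rows; variances are
    averaged too).
    """
    kwargs = {} if genotype_cap is None else {"genotype_cap": genotype_cap}
    space = make_space(l, len(tuple(alphabet)), tuple(alphabet), **kwargs)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    if "phenotype" not in df.columns and "value" in df.columns:
        df = df.rename(columns={"value": "phenotype"})  # prediction tables round-trip
    if not {"genotype", "phenotype"}.issubset(df.columns):
        raise ValueError(
            "table must have columns ['genotype', 'phenotype'] "
            f"(or 'value'), found {list(df.columns)}"
        )
    indices = np.empty(len(df), dtype=np.int64)
    for row, g in enumerate(df["genotype"].astype(str)):
        try:
            indices[row] = space.seq_to_index(g)
        except ValueError as exc:
            raise ValueError(f"line {row + 2}: {exc}") from None
    values = df["phenotype"].to_numpy(dtype=float)
    variances = (
        df["variance"].to_numpy(dtype=float) if "variance" in df.columns else None
    )
    if len(np.unique(indices)) != len(indices):
        if on_duplicate == "error":
            dup = indices[pd.Series(indices).duplicated()][0]
            raise ValueError(
                f"duplicate genotype {space.index_to_seq(int(dup))!r}; pass "
                "on_duplicate='mean' to average replicate rows"
            )
        if on_duplicate != "mean":
            raise ValueError("on_duplicate must be 'error' or 'mean'")
        frame = pd.DataFrame({"i": indices, "y": values})
        if variances is not None:
            frame["v"] = variances
        agg = frame.groupby("i", sort=True).mean()
        indices = agg.index.to_numpy()
        values = agg["y"].to_numpy()
        variances = agg["v"].to_numpy() if variances is not None else None
    return ObservationSet(
        space=space, indices=indices, y=values, noise_variance=variances
    )


def write_predictions(
    result: InterpolationResult | np.ndarray,
    path: str | Path,
    space: GenotypeSpace | None = None,
    sep: str = "\t",
    metadata: dict | None = None,
) -> Path:
    """Write a completed landscape as a table (one row per genotype, index
    order) plus a JSON sidecar with the space definition and settings."""
    path = Path(path)
    if isinstance(result, InterpolationResult):
        space = result.space
        values = result.f_hat
        in_sample = result.in_sample
        variance = result.prediction_variance
        extra = {"solver_diagnostics": {
            k: v for k, v in result.diagnostics.items() if _jsonable(v)
        }}
    else:
        if space is None:
            raise ValueError("space is required when writing a bare landscape")
        values = space._check_vector(result)
        in_sample = None
        variance = None
        extra = {}
    table = {
        "genotype": [space.index_to_seq(i) for i in range(space.n_genotypes)],
        "value": values,
    }
    if in_sample is not None:
        table["in_sample"] = in_sample.astype(int)
    if variance is not None:
        table["prediction_sd"] = np.sqrt(np.maximum(variance, 0.0))
    pd.DataFrame(table).to_csv(path, sep=sep, index=False)
    sidecar = {
        "space": {
            "l": space.l,
            "alpha": space.alpha,
            "alphabet": list(space.alphabet),
        },
        "n_genotypes": space.n_genotypes,
        "package_version": _package_version(),
        **extra,
        **(metadata or {}),
    }
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_landscape(
    path: str | Path, alphabet: Sequence[str] | str, l: int, sep: str | None = None,
    genotype_cap: int | None = None,
) -> tuple[GenotypeSpace, np.ndarray]:
    """Read a *complete* landscape table (all alpha^l genotypes present)."""
    obs = read_observations(path, alphabet, l, sep=sep, genotype_cap=genotype_cap)
    space = obs.space
    if obs.n_observed != space.n_genotypes:
        raise ValueError(
            f"complete landscape expected ({space.n_genotypes} genotypes), "
            f"table has {obs.n_observed}"
        )
    f = np.empty(space.n_genotypes)
    f[obs.indices] = obs.y
    return space, f


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False
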