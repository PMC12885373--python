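"""File formats: count tables, sample metadata, truth files, posterior archives.

Count tables are TSV with taxa as rows (first column = taxon id, header =
sample ids, integer cells).  Metadata is TSV with columns ``sample_id``,
``community``, ``cycles`` and optionally ``group``.  Ground-truth parameters
round-trip through JSON; posterior draws through a compressed numpy archive.
All tabular output is UTF-8 with 10-significant-digit floats so reruns are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compositions import ContrastMatrix
from .inference import PosteriorDraws
from .synthetic import CountMatrix, DesignMatrix, SimulationTruth, make_design

__all__ = [
    "design_from_metadata",
    "load_config",
    "read_count_table",
    "read_metadata",
    "read_posterior_archive",
    "read_truth",
    "write_count_table",
    "write_metadata",
    "write_posterior_archive",
    "write_truth",
]

FLOAT_FORMAT = "%.10g"


def read_count_table(path) -> CountMatrix:
    """Read a taxa-by-samples TSV count table.

    Rejects non-integer cells, duplicate taxon/sample ids and empty sample
    columns with descriptive errors.  Zeros are kept as zeros; use
    :meth:`CountMatrix.compositions` with a pseudo-count to extract strictly
    positive compositions.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError(f"{path}: duplicate taxon ids {sorted(set(df.index[df.index.duplicated()]))}")
    if df.columns.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    values = df.to_numpy()
    try:
        fvals = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in count table") from exc
    if np.any(~np.isfinite(fvals)) or np.any(fvals % 1 != 0):
        raise ValueError(f"{path}: count table cells must be integers")
    counts = fvals.astype(np.int64)
    empty = np.flatnonzero(counts.sum(axis=0) <= 0)
    if empty.size:
        raise ValueError(f"{path}: empty sample column(s): {[df.columns[i] for i in empty]}")
    return CountMatrix(counts, [str(t) for t in df.index], [str(s) for s in df.columns])


def write_count_table(cm: CountMatrix, path) -> None:
    df = pd.DataFrame(cm.counts, index=pd.Index(cm.taxon_ids, name="taxon_id"), columns=cm.sample_ids)
    df.to_csv(path, sep="\t")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, community, cycles[, group])."""
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "community": str})
    required = {"sample_id", "community", "cycles"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"{path}: metadata is missing columns {sorted(missing)}")
    cyc = pd.to_numeric(meta["cycles"], errors="coerce")
    if cyc.isna().any() or (cyc < 0).any() or (cyc % 1 != 0).any():
        raise ValueError(f"{path}: cycles must be nonnegative integers")
    meta["cycles"] = cyc.astype(int)
    if meta["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in metadata")
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def design_from_metadata(meta: pd.DataFrame, sample_ids: list[str] | None = None) -> DesignMatrix:
    """Build the one-hot + cycle design for samples in count-table order."""
    if sample_ids is not None:
        missing = set(sample_ids) - set(meta["sample_id"])
        if missing:
            raise ValueError(f"metadata lacks samples {sorted(missing)}")
        meta = meta.set_index("sample_id").loc[list(sample_ids)].reset_index()
    return make_design(meta["community"].tolist(), meta["cycles"].tolist())


def write_truth(truth: SimulationTruth, path, covariate_names=None) -> None:
    payload = {
        "lambda_true": np.asarray(truth.lambda_true).tolist(),
        "sigma_true": np.asarray(truth.sigma_true).tolist(),
        "seed": int(truth.seed),
        "depths": np.asarray(truth.depths).tolist(),
    }
    if covariate_names is not None:
        payload["covariate_names"] = list(covariate_names)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path) -> SimulationTruth:
    payload = json.loads(Path(path).read_text())
    return SimulationTruth(
        lambda_true=np.asarray(payload["lambda_true"], dtype=float),
        sigma_true=np.asarray(payload["sigma_true"], dtype=float),
        seed=int(payload["seed"]),
        depths=np.asarray(payload["depths"], dtype=np.int64),
    )


def write_posterior_archive(draws: PosteriorDraws, path) -> None:
    """Serialize posterior draws to a compressed numpy archive (.npz)."""
    np.savez_compressed(
        path,
        lambda_draws=draws.lambda_draws,
        sigma_draws=draws.sigma_draws,
        eta_draws=draws.eta_draws,
        eta_mode=draws.eta_mode,
        psi_matrix=draws.psi.matrix,
        psi_kind=np.array(draws.psi.basis_kind),
        covariate_names=np.array(draws.covariate_names),
        cycle_row=np.array(draws.cycle_row),
    )


def read_posterior_archive(path) -> PosteriorDraws:
    with np.load(path, allow_pickle=False) as z:
        return PosteriorDraws(
            lambda_draws=z["lambda_draws"],
            sigma_draws=z["sigma_draws"],
            eta_draws=z["eta_draws"],
            psi=ContrastMatrix(z["psi_matrix"], basis_kind=str(z["psi_kind"])),
            covariate_names=[str(c) for c in z["covariate_names"]],
            cycle_row=int(z["cycle_row"]),
            eta_mode=z["eta_mode"],
        )


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
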