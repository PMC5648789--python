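"""File I/O: expression readers (dense TSV/CSV and MatrixMarket MTX
with sidecar name files), the low-expression filter, and result
writers."""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .em import ScPLSResults

__all__ = [
    "RunConfig",
    "FilterReport",
    "read_expression",
    "read_gene_list",
    "filter_low_expression",
    "write_outputs",
]


@dataclass
class RunConfig:
    """Configuration of one command-line run, echoed into the manifest."""

    input_path: str = ""
    controls_path: str = ""
    transform: str = "counts"        # counts -> log1p+center | pretransformed
    kz: Optional[int] = None
    ku: Optional[int] = None
    select: bool = False
    kz_grid: Sequence[int] = (1, 2, 3)
    ku_grid: Sequence[int] = tuple(range(1, 11))
    algorithm: str = "chunks"
    chunk_size: int = 500
    tol: float = 1e-4
    max_iter: int = 500
    seed: int = 0
    output_dir: str = "."


def _check_names(names, what):
    names = [str(x) for x in names]
    seen, dups = set(), []
    for x in names:
        if x in seen:
            dups.append(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {what} names: {sorted(set(dups))}")
    return np.asarray(names, dtype=object)


def read_expression(path, fmt: Optional[str] = None,
                    cells_as: str = "rows") -> pd.DataFrame:
    """Read an expression matrix into a cells × genes DataFrame.

    ``fmt`` is "tsv", "csv" or "mtx" (inferred from the extension when
    omitted).  MTX input expects sidecar name files ``<path>.rows`` and
    ``<path>.cols`` (one name per line).  ``cells_as`` declares whether
    cells are on the rows or columns of the file — orientation is never
    guessed from the data.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower().lstrip(".")
        fmt = {"tsv": "tsv", "txt": "tsv", "csv": "csv",
               "mtx": "mtx"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}; "
                             "pass fmt explicitly")
    if cells_as not in {"rows", "columns"}:
        raise ValueError("cells_as must be 'rows' or 'columns'")
    if fmt == "mtx":
        from scipy import io as spio

        mat = np.asarray(spio.mmread(path).todense(), dtype=float)
        rows = _check_names(
            Path(str(path) + ".rows").read_text().split(), "row")
        cols = _check_names(
            Path(str(path) + ".cols").read_text().split(), "column")
        if mat.shape != (len(rows), len(cols)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match name files "
                f"({len(rows)} rows, {len(cols)} cols)")
        frame = pd.DataFrame(mat, index=rows, columns=cols)
    else:
        sep = "\t" if fmt == "tsv" else ","
        # pandas silently renames duplicate header names; check the raw
        # header line first
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)
        _check_names([h for h in header if h != ""], "header")
        frame = pd.read_csv(path, sep=sep, index_col=0)
        bad = frame.apply(pd.to_numeric, errors="coerce")
        if bad.isna().to_numpy().any():
            i, j = np.argwhere(bad.isna().to_numpy())[0]
            raise ValueError(
                f"non-numeric value at row {frame.index[i]!r}, "
                f"column {frame.columns[j]!r} in {path}")
        frame = bad
        frame.index = _check_names(frame.index, "row")
        frame.columns = _check_names(frame.columns, "column")
    if cells_as == "columns":
        frame = frame.T
    _check_names(frame.columns, "gene")
    _check_names(frame.index, "cell")
    return frame


def read_gene_list(path) -> list:
    """Plain-text gene list, one name per line (blank lines ignored)."""
    return [ln.strip() for ln in Path(path).read_text().splitlines()
            if ln.strip()]


@dataclass
class FilterReport:
    """Names kept and dropped by the low-expression filter."""

    kept_targets: list = field(default_factory=list)
    dropped_targets: list = field(default_factory=list)
    kept_controls: list = field(default_factory=list)
    dropped_controls: list = field(default_factory=list)


def filter_low_expression(counts: pd.DataFrame, control_genes,
                          min_count_gene: int = 5,
                          min_count_control: int = 1,
                          min_cell_fraction: float = 1 / 3):
    """Drop lowly expressed genes from a cells × genes count frame.

    A target gene is kept iff its count is at least ``min_count_gene``
    in strictly more than ``min_cell_fraction`` of cells; a control gene
    iff its count is at least ``min_count_control`` in strictly more
    than that fraction.  Returns ``(filtered_frame, FilterReport)``.
    """
    if not isinstance(counts, pd.DataFrame):
        raise TypeError("counts must be a cells × genes DataFrame")
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError("counts must be numeric")
    if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be nonnegative integers")
    control_genes = {str(g) for g in control_genes}
    is_control = np.isin(counts.columns.astype(str), list(control_genes))
    n = counts.shape[0]
    threshold = np.where(is_control, min_count_control, min_count_gene)
    frac_expressed = (vals >= threshold[None, :]).sum(axis=0) / n
    keep = frac_expressed > min_cell_fraction  # strictly more than
    report = FilterReport(
        kept_targets=list(counts.columns[keep & ~is_control]),
        dropped_targets=list(counts.columns[~keep & ~is_control]),
        kept_controls=list(counts.columns[keep & is_control]),
        dropped_controls=list(counts.columns[~keep & is_control]),
    )
    if is_control.any() and not report.kept_controls:
        raise ValueError(
            "all control genes removed by the filter; the model cannot "
            "be fitted without controls")
    return counts.loc[:, keep], report


def write_outputs(fit: ScPLSResults, outdir, config: Optional[RunConfig] = None,
                  write_mtx: bool = False) -> None:
    """Write fit outputs: corrected matrix (TSV, optional MTX),
    loadings, posterior confounding-factor means, per-gene PVE table,
    log-likelihood trace, BIC grid if a selection was run, and a
    machine-readable run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = fit.data
    cells = data.cell_ids if data is not None else None
    targets = data.target_ids if data is not None else None
    controls = data.control_ids if data is not None else None

    corrected = pd.DataFrame(fit.corrected_Y, index=cells, columns=targets)
    corrected.to_csv(outdir / "corrected.tsv", sep="\t",
                     float_format="%.17g")
    if write_mtx:
        from scipy import io as spio
        from scipy import sparse

        spio.mmwrite(outdir / "corrected.mtx",
                     sparse.csr_matrix(fit.corrected_Y))
        Path(outdir / "corrected.mtx.rows").write_text(
            "\n".join(map(str, cells)) + "\n")
        Path(outdir / "corrected.mtx.cols").write_text(
            "\n".join(map(str, targets)) + "\n")

    pd.DataFrame(fit.params.Lambda_x, index=controls).to_csv(
        outdir / "lambda_x.tsv", sep="\t")
    pd.DataFrame(fit.params.Lambda_y, index=targets).to_csv(
        outdir / "lambda_y.tsv", sep="\t")
    pd.DataFrame(fit.params.Lambda_u, index=targets).to_csv(
        outdir / "lambda_u.tsv", sep="\t")
    pd.DataFrame(fit.Ez, index=cells).to_csv(
        outdir / "posterior_z.tsv", sep="\t")
    np.savetxt(outdir / "psi_x.tsv", fit.params.psi_x, delimiter="\t")
    pd.DataFrame({
        "gene": targets,
        "pve_confounding": fit.pve_confounding,
        "pve_biological": fit.pve_biological,
        "psi": fit.params.psi_y,
    }).to_csv(outdir / "pve.tsv", sep="\t", index=False)
    pd.DataFrame({"iteration": np.arange(len(fit.loglik_trace)),
                  "loglik": fit.loglik_trace}).to_csv(
        outdir / "loglik_trace.tsv", sep="\t", index=False)
    if fit.bic_grid is not None:
        fit.bic_grid.to_csv(outdir / "bic_grid.tsv", sep="\t", index=False)

    import scpls

    manifest = {
        "package": "scpls",
        "version": scpls.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "kz": fit.kz,
        "ku": fit.ku,
        "loglik": fit.loglik,
        "bic": fit.bic,
        "converged": bool(fit.converged),
        "n_iter": int(fit.n_iter),
        "config": None if config is None else asdict(config),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str) + "\n")
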