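"""Container and table I/O.

The native container is a single HDF5 file with groups ``/space``,
``/runs/<id>`` and ``/maps`` (plus optional ``/truth`` and
``/expression`` written by the synthetic generator).  Small maps and the
space definition can also be exported as TSV.  Grayordinate indexing is
0-based everywhere, including in files, and loaders verify the index
column is exactly ``0..G-1`` so data are never silently reordered.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import h5py

from .model import (
    BoldRun,
    CohortDesign,
    ExpressionMatrix,
    FormatError,
    GrayordinateSpace,
    ScalarMap,
    ValidationError,
)

_STR = h5py.string_dtype(encoding="utf-8")


def _write_space(grp: h5py.Group, space: GrayordinateSpace) -> None:
    grp.create_dataset("structure", data=space.structure.astype(_STR))
    grp.create_dataset("network", data=space.network.astype(_STR))
    grp.create_dataset("parcel", data=space.parcel)
    grp.create_dataset("edges", data=space.edges)


def _read_space(grp: h5py.Group) -> GrayordinateSpace:
    return GrayordinateSpace(
        structure=grp["structure"].asstr()[...],
        network=grp["network"].asstr()[...],
        parcel=grp["parcel"][...],
        edges=grp["edges"][...],
    )


def save_cohort(path, space, design, runs, truth=None, expression=None) -> None:
    """Write a cohort container.

    ``runs`` is a dict run_id -> :class:`BoldRun`.  ``truth`` is an
    optional dict of arrays written under ``/truth``; ``expression`` an
    optional :class:`ExpressionMatrix` written under ``/expression``.
    """
    with h5py.File(path, "w") as f:
        _write_space(f.create_group("space"), space)
        d = f.create_group("design")
        for col in ("subject", "condition", "run_id"):
            d.create_dataset(col, data=design.table[col].astype(str).to_numpy(dtype=_STR))
        d.create_dataset("session", data=design.table["session"].to_numpy(dtype=np.int64))
        if design.excluded:
            ex = d.create_group("excluded")
            for subj, reason in sorted(design.excluded.items()):
                ex.attrs[str(subj)] = str(reason)
        rg = f.create_group("runs")
        for rid in sorted(runs):
            run = runs[rid]
            g = rg.create_group(rid)
            g.attrs["subject"] = run.subject
            g.attrs["condition"] = run.condition
            g.attrs["session"] = run.session
            g.attrs["tr"] = run.tr
            g.create_dataset("bold", data=run.bold)
            g.create_dataset("motion", data=run.motion)
            g.create_dataset("ventricle_ts", data=run.ventricle_ts)
            g.create_dataset("wm_ts", data=run.wm_ts)
        if truth is not None:
            tg = f.create_group("truth")
            for key in sorted(truth):
                tg.create_dataset(key, data=np.asarray(truth[key]))
        if expression is not None:
            eg = f.create_group("expression")
            eg.create_dataset("genes", data=np.asarray(expression.genes, dtype=_STR))
            eg.create_dataset("values", data=expression.values)


def load_cohort(path):
    """Read a cohort container -> (space, design, runs dict).

    Raises :class:`FormatError` if the space block is missing and
    :class:`ValidationError` (naming the run) if a run is inconsistent.
    """
    with h5py.File(path, "r") as f:
        if "space" not in f:
            raise FormatError(f"{path}: missing /space block")
        space = _read_space(f["space"])
        if "runs" not in f or not len(f["runs"]):
            raise FormatError(f"{path}: no run blocks")
        runs = {}
        for rid, g in f["runs"].items():
            try:
                runs[rid] = BoldRun(
                    subject=g.attrs["subject"],
                    condition=g.attrs["condition"],
                    session=int(g.attrs["session"]),
                    bold=g["bold"][...],
                    tr=float(g.attrs["tr"]),
                    motion=g["motion"][...],
                    ventricle_ts=g["ventricle_ts"][...],
                    wm_ts=g["wm_ts"][...],
                )
            except ValidationError:
                raise
            except (KeyError, ValueError) as exc:
                raise ValidationError(f"run {rid}: {exc}") from exc
            if runs[rid].n_gray != space.n_gray:
                raise ValidationError(
                    f"run {rid}: bold has {runs[rid].n_gray} grayordinates, "
                    f"space has {space.n_gray}"
                )
        if "design" in f:
            d = f["design"]
            table = pd.DataFrame(
                {
                    "subject": d["subject"].asstr()[...],
                    "condition": d["condition"].asstr()[...],
                    "session": d["session"][...],
                    "run_id": d["run_id"].asstr()[...],
                }
            )
            excluded = {}
            if "excluded" in d:
                excluded = {k: v for k, v in d["excluded"].attrs.items()}
            design = CohortDesign(table=table, excluded=excluded)
        else:
            design = _design_from_runs(runs)
    return space, design, runs


def load_truth(path) -> dict:
    with h5py.File(path, "r") as f:
        if "truth" not in f:
            raise FormatError(f"{path}: no /truth group")
        return {k: f["truth"][k][...] for k in f["truth"]}


def load_expression(path) -> ExpressionMatrix:
    with h5py.File(path, "r") as f:
        if "expression" not in f:
            raise FormatError(f"{path}: no /expression group")
        g = f["expression"]
        return ExpressionMatrix(
            genes=list(g["genes"].asstr()[...]), values=g["values"][...]
        )


def _design_from_runs(runs) -> CohortDesign:
    rows = [
        {
            "subject": r.subject,
            "condition": r.condition,
            "session": r.session,
            "run_id": rid,
        }
        for rid, r in sorted(runs.items())
    ]
    return CohortDesign(table=pd.DataFrame(rows))


# ---------------------------------------------------------------- maps

def save_map(map_: ScalarMap, path, format: str = "tsv") -> None:
    """Write a scalar map as TSV (index, value) or into an HDF5 container."""
    if format == "tsv":
        df = pd.DataFrame({"index": np.arange(map_.values.size), "value": map_.values})
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif format == "container":
        with h5py.File(path, "a") as f:
            grp = f.require_group("maps")
            name = map_.kind
            i = 0
            while name in grp:
                i += 1
                name = f"{map_.kind}_{i}"
            ds = grp.create_dataset(name, data=map_.values)
            ds.attrs["kind"] = map_.kind
            ds.attrs["space_ref"] = map_.space_ref
    else:
        raise ValueError(f"unknown map format {format!r} (use 'tsv' or 'container')")


def load_map(path, kind: str = "z", format: str = "tsv", name: str | None = None) -> ScalarMap:
    if format == "tsv":
        df = pd.read_csv(path, sep="\t")
        idx = df["index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(df))):
            raise FormatError(f"{path}: index column is not 0..G-1 in order")
        return ScalarMap(values=df["value"].to_numpy(), kind=kind)
    elif format == "container":
        with h5py.File(path, "r") as f:
            ds = f["maps"][name if name is not None else kind]
            return ScalarMap(
                values=ds[...],
                kind=str(ds.attrs.get("kind", kind)),
                space_ref=str(ds.attrs.get("space_ref", "")),
            )
    raise ValueError(f"unknown map format {format!r}")


def save_space_tsv(space: GrayordinateSpace, labels_path, edges_path) -> None:
    pd.DataFrame(
        {
            "index": np.arange(space.n_gray),
            "structure": space.structure,
            "network": space.network,
            "parcel": space.parcel,
        }
    ).to_csv(labels_path, sep="\t", index=False)
    pd.DataFrame(space.edges, columns=["i", "j"]).to_csv(edges_path, sep="\t", index=False)


def load_space_tsv(labels_path, edges_path) -> GrayordinateSpace:
    lab = pd.read_csv(labels_path, sep="\t")
    if not np.array_equal(lab["index"].to_numpy(), np.arange(len(lab))):
        raise FormatError(f"{labels_path}: index column is not 0..G-1 in order")
    edges = pd.read_csv(edges_path, sep="\t")[["i", "j"]].to_numpy()
    return GrayordinateSpace(
        structure=lab["structure"].to_numpy(dtype=object),
        network=lab["network"].to_numpy(dtype=object),
        parcel=lab["parcel"].to_numpy(),
        edges=edges,
    )


def save_expression_tsv(expr: ExpressionMatrix, path) -> None:
    cols = [f"parcel_{i:03d}" for i in range(expr.n_parcels)]
    df = pd.DataFrame(expr.values, index=expr.genes, columns=cols)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.17g")


def load_expression_tsv(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return ExpressionMatrix(genes=list(df.index), values=df.to_numpy())
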