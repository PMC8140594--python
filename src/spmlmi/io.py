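"""File I/O: TSV tables, HDF5 network containers, and run manifests."""

from __future__ import annotations

import hashlib
import json
import sys
import time
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .network import BilayerNetwork, InteractionNetwork
from .similarity import ExpressionMatrix, SimilarityNetwork

__all__ = [
    "write_expression_tsv",
    "write_interactions_tsv",
    "write_similarity_tsv",
    "save_bilayer",
    "load_bilayer",
    "save_scores",
    "load_scores",
    "write_ranked_tsv",
    "write_manifest",
]


def write_expression_tsv(em: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(em.values, index=em.rna_ids, columns=em.condition_ids)
    df.to_csv(path, sep="\t", index_label="id", float_format="%.6g")


def write_interactions_tsv(lm: InteractionNetwork, path: str | Path) -> None:
    rows, cols = np.nonzero(lm.matrix)
    with open(path, "w") as fh:
        for i, j in zip(rows, cols):
            fh.write(f"{lm.lnc_ids[i]}\t{lm.mi_ids[j]}\n")


def write_similarity_tsv(net: SimilarityNetwork, path: str | Path) -> None:
    df = pd.DataFrame(net.weights, index=net.node_ids, columns=net.node_ids)
    df.to_csv(path, sep="\t", index_label="id", float_format="%.10g")


def save_bilayer(bn: BilayerNetwork, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("A", data=bn.A, track_times=False)
        f.create_dataset(
            "node_ids",
            data=np.array(bn.node_ids, dtype=h5py.string_dtype()),
            track_times=False,
        )
        f.attrs["n_lnc"] = bn.n_lnc
        f.attrs["n_mi"] = bn.n_mi
        f.attrs["lm_weight"] = bn.lm_weight


def load_bilayer(path: str | Path) -> BilayerNetwork:
    with h5py.File(path, "r") as f:
        return BilayerNetwork(
            A=f["A"][()],
            n_lnc=int(f.attrs["n_lnc"]),
            n_mi=int(f.attrs["n_mi"]),
            node_ids=[s.decode() for s in f["node_ids"][()]],
            lm_weight=float(f.attrs.get("lm_weight", 1.0)),
        )


def save_scores(scores: np.ndarray, path: str | Path, **attrs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("scores", data=scores, track_times=False)
        for k, v in attrs.items():
            if v is not None:
                f.attrs[k] = v


def load_scores(path: str | Path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["scores"][()]


def write_ranked_tsv(ranked: list[tuple[str, str, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("lnc_id\tmi_id\tscore\trank\n")
        for rank, (lnc, mi, score) in enumerate(ranked, start=1):
            fh.write(f"{lnc}\t{mi}\t{score:.10g}\t{rank}\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_path: str | Path,
    params: dict,
    inputs: list[str | Path] = (),
) -> Path:
    """Record command line, parameters, seed, version, and input checksums.

    Written next to the primary output as ``<output>.manifest.json`` so every
    run is reproducible from its artefacts alone.
    """
    from . import __version__

    out_path = Path(out_path)
    manifest = {
        "command": sys.argv,
        "params": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                   for k, v in params.items()},
        "version": __version__,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    mpath = out_path.with_name(out_path.name + ".manifest.json")
    mpath.write_text(json.dumps(manifest, indent=2) + "\n")
    return mpath
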