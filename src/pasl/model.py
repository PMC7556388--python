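"""End-to-end model: standardize, learn D = [D1; D2], project with D⁺.

Training data are standardized feature-wise with their own means and
standard deviations; those statistics are frozen in the model so that
new samples are transformed without estimating anything from them.  The
dictionary stacks the geneset-constrained inference atoms on top of the
discovered sparse atoms; scores are the least-squares projection onto
its row space, ``L = X_std · D⁺`` with ``D⁺`` the Moore–Penrose
pseudoinverse computed once at fit time.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .discovery import discover_dictionary
from .genesets import MembershipMatrix
from .inference import Atom, InferenceTrace, infer_dictionary

__all__ = [
    "Standardizer",
    "PaslModel",
    "fit",
    "transform",
    "reconstruction_error",
    "save",
    "load",
]

_FORMAT_VERSION = 1


@dataclass
class Standardizer:
    """Feature-wise z-scoring with frozen training statistics.

    Zero-variance training features (σ undefined for scaling purposes)
    are masked to exactly 0 after centering rather than propagating NaN;
    the mask is kept so the choice is visible in the saved model.
    """

    means: np.ndarray
    stds: np.ndarray
    zero_variance_mask: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        means = X.mean(axis=0)
        stds = X.std(axis=0, ddof=1)
        # constant columns have std 0 up to float noise from the centering
        mask = stds <= 1e-12 * (1.0 + np.abs(means))
        safe = np.where(mask, 1.0, stds)
        return cls(means=means, stds=safe, zero_variance_mask=mask)

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.means) / self.stds
        if self.zero_variance_mask.any():
            Z[:, self.zero_variance_mask] = 0.0
        return Z


@dataclass
class PaslModel:
    """Fitted PASL model: standardizer + dictionary + projection operator.

    ``dictionary`` is the ``a × p`` stack of unit-norm atoms (inference
    first, then discovery) and ``pinv`` its ``p × a`` Moore–Penrose
    pseudoinverse.  ``atoms`` carries per-atom provenance: the source
    geneset and occurrence for inference atoms, ``DISCOVERED_k`` for
    discovery atoms.  ``scores_train`` is the training-data projection.
    """

    standardizer: Standardizer
    feature_ids: list[str]
    atoms: list[Atom]
    dictionary: np.ndarray
    pinv: np.ndarray
    trace: InferenceTrace
    params: dict
    scores_train: pd.DataFrame | None = None
    sample_ids_train: list[str] = field(default_factory=list)

    @property
    def atom_names(self) -> list[str]:
        return [a.name for a in self.atoms]

    @property
    def n_atoms(self) -> int:
        return self.dictionary.shape[0]

    @property
    def n_inference_atoms(self) -> int:
        return sum(1 for a in self.atoms if a.phase == "inference")


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError("expression input must be a pandas DataFrame (samples × features)")


def fit(
    X_train: pd.DataFrame,
    G: MembershipMatrix,
    t: float = 0.9,
    lam: float | None = 1.0 / 3.0,
    a1: int = 500,
    a2: int = 0,
    m: int = 2000,
    stop_tol: float = 1e-3,
    seed: int | None = None,
) -> PaslModel:
    """Fit a PASL model on training expression data.

    ``X_train`` is samples × features with feature ids as columns,
    aligned with ``G``.  ``a1``/``a2`` bound the inference/discovery atom
    counts, ``m`` is the discovery cardinality, ``t`` the reorder
    threshold and ``lam`` the Box-Cox exponent of the size
    normalization.  The fit is deterministic; ``seed`` is recorded for
    provenance only.
    """
    X_train = _as_frame(X_train)
    features = [str(c) for c in X_train.columns]
    if features != list(G.feature_ids):
        raise ValueError(
            "feature ids of the expression matrix and the membership matrix "
            "are not aligned; build the membership matrix against these columns"
        )
    values = X_train.to_numpy(dtype=np.float64)
    bad = ~np.isfinite(values)
    if bad.any():
        cols = sorted({features[j] for j in np.unique(np.where(bad)[1])})
        raise ValueError(f"non-finite values in training features: {cols[:20]}")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 training samples")

    standardizer = Standardizer.fit(values)
    Z = standardizer.transform(values)

    d1_atoms, trace = infer_dictionary(Z, G, t=t, lam=lam, max_atoms=a1, stop_tol=stop_tol)

    R = Z.copy()
    for atom in d1_atoms:
        R -= np.outer(R @ atom.loading, atom.loading)
    d2_atoms = discover_dictionary(R, a2, m) if a2 > 0 else []

    atoms: list[Atom] = list(d1_atoms)
    for k, s in enumerate(d2_atoms, start=1):
        atoms.append(
            Atom(
                loading=s.loading,
                name=f"DISCOVERED_{k}",
                phase="discovery",
                explained_variance=s.explained_variance,
            )
        )

    p = len(features)
    D = np.vstack([a.loading for a in atoms]) if atoms else np.empty((0, p))
    Dplus = np.linalg.pinv(D, rcond=1e-10) if atoms else np.empty((p, 0))

    model = PaslModel(
        standardizer=standardizer,
        feature_ids=features,
        atoms=atoms,
        dictionary=D,
        pinv=Dplus,
        trace=trace,
        params={
            "t": t,
            "lam": lam,
            "a1": a1,
            "a2": a2,
            "m": m,
            "stop_tol": stop_tol,
            "seed": seed,
        },
    )
    model.sample_ids_train = [str(s) for s in X_train.index]
    if model.n_atoms > 0:
        model.scores_train = transform(model, X_train)
    return model


def transform(model: PaslModel, X: pd.DataFrame) -> pd.DataFrame:
    """Project samples into the latent space: ``L = standardize(X) · D⁺``.

    Features are aligned by identifier (columns reordered as needed);
    features the model knows but ``X`` lacks raise an error — no
    imputation.  Nothing is estimated from ``X``.
    """
    X = _as_frame(X)
    if model.n_atoms == 0:
        raise ValueError("model has an empty dictionary; nothing to project onto")
    cols = [str(c) for c in X.columns]
    missing = [f for f in model.feature_ids if f not in set(cols)]
    if missing:
        raise ValueError(f"input lacks {len(missing)} model features, e.g. {missing[:10]}")
    aligned = X.loc[:, model.feature_ids].to_numpy(dtype=np.float64)
    Z = model.standardizer.transform(aligned)
    L = Z @ model.pinv
    return pd.DataFrame(L, index=X.index, columns=model.atom_names)


def reconstruction_error(model: PaslModel, X: pd.DataFrame) -> float:
    """Relative reconstruction error ``‖Z − L·D‖²_F / ‖Z‖²_F``.

    ``Z`` is the standardized input; the value lies in [0, 1] because
    ``L·D`` is an orthogonal projection of ``Z`` onto the row space of
    the dictionary.
    """
    X = _as_frame(X)
    aligned = X.loc[:, model.feature_ids].to_numpy(dtype=np.float64)
    Z = model.standardizer.transform(aligned)
    total = float(np.sum(Z * Z))
    if total == 0.0:
        raise ValueError("standardized input has zero norm")
    L = transform(model, X).to_numpy()
    E = Z - L @ model.dictionary
    return float(np.sum(E * E)) / total


def _fmt(x: float) -> str:
    return repr(float(x))  # shortest representation that round-trips float64


def save(model: PaslModel, path) -> None:
    """Persist a model as a directory (or ``.zip``) of text artifacts.

    ``dictionary.tsv`` holds sparse (atom_index, atom_name, feature_id,
    coefficient) triplets, ``standardizer.tsv`` the training statistics,
    ``trace.tsv`` the fit trace, and ``meta.json`` the hyper-parameters
    and atom provenance.  The round-trip is lossless: coefficients are
    written with full float64 precision.
    """
    path = Path(path)
    as_zip = path.suffix == ".zip"

    dict_lines = ["atom_index\tatom_name\tfeature_id\tcoefficient"]
    for i, atom in enumerate(model.atoms):
        for j in atom.support:
            dict_lines.append(
                f"{i}\t{atom.name}\t{model.feature_ids[j]}\t{_fmt(atom.loading[j])}"
            )
    std_lines = ["feature_id\tmean\tstd\tzero_variance"]
    s = model.standardizer
    for j, f in enumerate(model.feature_ids):
        std_lines.append(f"{f}\t{_fmt(s.means[j])}\t{_fmt(s.stds[j])}\t{int(s.zero_variance_mask[j])}")

    meta = {
        "format_version": _FORMAT_VERSION,
        "params": model.params,
        "n_atoms": model.n_atoms,
        "feature_ids": model.feature_ids,
        "sample_ids_train": model.sample_ids_train,
        "atoms": [
            {
                "name": a.name,
                "phase": a.phase,
                "geneset_index": a.geneset_index,
                "geneset_name": a.geneset_name,
                "occurrence": a.occurrence,
                "explained_variance": a.explained_variance,
            }
            for a in model.atoms
        ],
        "trace": {
            "t": model.trace.t,
            "lam": model.trace.lam,
            "max_atoms": model.trace.max_atoms,
            "stop_tol": model.trace.stop_tol,
            "initial_ordering": model.trace.initial_ordering,
            "records": model.trace.records,
            "n_reorders": model.trace.n_reorders,
            "notes": model.trace.notes,
        },
    }
    trace_tsv = model.trace.to_frame().to_csv(sep="\t", index=False)

    files = {
        "dictionary.tsv": "\n".join(dict_lines) + "\n",
        "standardizer.tsv": "\n".join(std_lines) + "\n",
        "trace.tsv": trace_tsv,
        "meta.json": json.dumps(meta, indent=1),
    }
    if as_zip:
        with zipfile.ZipFile(path, "w") as zf:
            for name, content in files.items():
                zf.writestr(name, content)
    else:
        path.mkdir(parents=True, exist_ok=True)
        for name, content in files.items():
            (path / name).write_text(content)


def load(path) -> PaslModel:
    """Load a model saved by :func:`save`; the inverse round-trips exactly."""
    path = Path(path)

    def read(name: str) -> str:
        if path.suffix == ".zip":
            with zipfile.ZipFile(path) as zf:
                return zf.read(name).decode()
        f = path / name
        if not f.exists():
            raise ValueError(f"model archive {path} is missing {name}")
        return f.read_text()

    try:
        meta = json.loads(read("meta.json"))
    except (json.JSONDecodeError, KeyError, zipfile.BadZipFile) as e:
        raise ValueError(f"corrupt model archive {path}: {e}") from None
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"model format version {meta.get('format_version')} not supported "
            f"(expected {_FORMAT_VERSION})"
        )
    feature_ids = [str(f) for f in meta["feature_ids"]]
    p = len(feature_ids)
    col = {f: j for j, f in enumerate(feature_ids)}

    std_df = pd.read_csv(
        _as_buffer(read("standardizer.tsv")), sep="\t", dtype={"feature_id": str},
        float_precision="round_trip",
    )
    if list(std_df["feature_id"]) != feature_ids:
        raise ValueError("standardizer features disagree with meta.json")
    standardizer = Standardizer(
        means=std_df["mean"].to_numpy(float),
        stds=std_df["std"].to_numpy(float),
        zero_variance_mask=std_df["zero_variance"].to_numpy(bool),
    )

    atoms: list[Atom] = []
    for a in meta["atoms"]:
        atoms.append(
            Atom(
                loading=np.zeros(p),
                name=a["name"],
                phase=a["phase"],
                geneset_index=a["geneset_index"],
                geneset_name=a["geneset_name"],
                occurrence=a["occurrence"],
                explained_variance=a["explained_variance"],
            )
        )
    dict_df = pd.read_csv(
        _as_buffer(read("dictionary.tsv")), sep="\t", dtype={"feature_id": str},
        float_precision="round_trip",
    )
    nnz = 0
    for i, fid, coef in zip(dict_df["atom_index"], dict_df["feature_id"], dict_df["coefficient"]):
        atoms[int(i)].loading[col[fid]] = float(coef)
        nnz += 1
    if nnz != len(dict_df):
        raise ValueError("dictionary triplet count mismatch")

    tr = meta["trace"]
    trace = InferenceTrace(
        t=tr["t"],
        lam=tr["lam"],
        max_atoms=tr["max_atoms"],
        stop_tol=tr["stop_tol"],
        initial_ordering=[tuple(x) for x in tr["initial_ordering"]],
        records=tr["records"],
        n_reorders=tr["n_reorders"],
        notes=tr["notes"],
    )
    D = np.vstack([a.loading for a in atoms]) if atoms else np.empty((0, p))
    Dplus = np.linalg.pinv(D, rcond=1e-10) if atoms else np.empty((p, 0))
    return PaslModel(
        standardizer=standardizer,
        feature_ids=feature_ids,
        atoms=atoms,
        dictionary=D,
        pinv=Dplus,
        trace=trace,
        params=meta["params"],
        sample_ids_train=[str(s) for s in meta.get("sample_ids_train", [])],
    )


def _as_buffer(text: str):
    import io

    return io.StringIO(text)
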