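"""Latent-space diagnostics: embedding, neighbor retrieval, sparsity.

All analysis runs on canonical-SMILES latents obtained in evaluation
mode (training only ever saw enumerated strings).  Similarity is
measured three ways: cosine and Euclidean in the latent space, and
Tanimoto over path-based binary fingerprints as the structural
baseline.  Sparsity is summarized by three traces over the latent
matrix: the number of dimensions nonzero for every molecule, the mean
per-molecule nonzero count, and the maximum count.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdmolops

from .model import FragNet
from .smiles_data import MoleculeRecord, SmilesParseError, TokenVocabulary, \
    encode_sequence, tokenize


@dataclass(frozen=True)
class LatentMatrix:
    """Canonical-SMILES projection vectors, one row per molecule."""

    ids: list[str]
    vectors: np.ndarray         # (n, d_model)
    source_temperature: float

    def row(self, mol_id: str) -> np.ndarray:
        return self.vectors[self.ids.index(mol_id)]

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id"] + [f"z{i}" for i in range(self.vectors.shape[1])])
            for mid, vec in zip(self.ids, self.vectors):
                w.writerow([mid] + [f"{v:.10g}" for v in vec])

    @classmethod
    def from_csv(cls, path: str | Path,
                 source_temperature: float = float("nan")) -> "LatentMatrix":
        ids, rows = [], []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader)
            for row in reader:
                ids.append(row[0])
                rows.append([float(v) for v in row[1:]])
        return cls(ids=ids, vectors=np.array(rows),
                   source_temperature=source_temperature)


@dataclass(frozen=True)
class SimilarityResult:
    query_id: str
    neighbor_id: str
    cosine: float
    euclidean: float
    tanimoto: float


@dataclass(frozen=True)
class DimensionPopulationSummary:
    """The three latent-sparsity traces plus the dimensionality."""

    always_nonzero: int
    mean_nonzero: float
    max_nonzero: int
    dimensionality: int


def embed_corpus(records: list[MoleculeRecord], model: FragNet,
                 vocab: TokenVocabulary) -> LatentMatrix:
    """Project every canonical SMILES in evaluation mode (deterministic)."""
    missing: list[str] = []
    for rec in records:
        for tok in tokenize(rec.canonical_smiles):
            if tok not in vocab.token_to_index:
                missing.append(f"{rec.id}:{tok}")
    if missing:
        raise ValueError(f"tokens outside checkpoint vocabulary: {missing}")
    vecs = []
    for rec in records:
        seq = encode_sequence(rec.canonical_smiles, vocab, model.cfg.max_len)
        vecs.append(model.embed_sequence(seq))
    return LatentMatrix(ids=[r.id for r in records], vectors=np.stack(vecs),
                        source_temperature=model.cfg.temperature)


def fingerprint(smiles: str, fp_size: int = 2048, max_path: int = 7):
    """Path-based binary substructure fingerprint (RDKit RDKFingerprint)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    return rdmolops.RDKFingerprint(mol, fpSize=fp_size, maxPath=max_path)


def tanimoto(smiles_a: str, smiles_b: str, **fp_kwargs) -> float:
    """|A & B| / |A | B| over the on-bit sets of the two fingerprints."""
    fa = fingerprint(smiles_a, **fp_kwargs)
    fb = fingerprint(smiles_b, **fp_kwargs)
    return float(DataStructs.TanimotoSimilarity(fa, fb))


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


def neighbor_query(query: MoleculeRecord, latents: LatentMatrix,
                   corpus: list[MoleculeRecord], metric: str,
                   k: int, model: FragNet | None = None,
                   vocab: TokenVocabulary | None = None) -> list[SimilarityResult]:
    """Top-k neighbors of a query under one metric, all metrics reported.

    Cosine and Tanimoto rank descending, Euclidean ascending; ties break
    lexicographically by neighbor id.  If the query is absent from the
    latent matrix it is embedded with the supplied model.
    """
    if metric not in {"cosine", "euclidean", "tanimoto"}:
        raise ValueError(f"unknown metric {metric!r}")
    if k > len(latents.ids):
        raise ValueError(f"k={k} exceeds corpus size {len(latents.ids)}")
    if query.id in latents.ids:
        qvec = latents.row(query.id)
    else:
        if model is None or vocab is None:
            raise ValueError("query not in corpus; pass model and vocab")
        seq = encode_sequence(query.canonical_smiles, vocab, model.cfg.max_len)
        qvec = model.embed_sequence(seq)
    by_id = {r.id: r for r in corpus}
    results = []
    for mid, vec in zip(latents.ids, latents.vectors):
        results.append(SimilarityResult(
            query_id=query.id, neighbor_id=mid,
            cosine=_cosine(qvec, vec),
            euclidean=float(np.linalg.norm(qvec - vec)),
            tanimoto=tanimoto(query.canonical_smiles,
                              by_id[mid].canonical_smiles)))
    if metric == "euclidean":
        results.sort(key=lambda r: (r.euclidean, r.neighbor_id))
    else:
        results.sort(key=lambda r: (-getattr(r, metric), r.neighbor_id))
    return results[:k]


def similarity_scatter(query_id: str, latents_a: LatentMatrix,
                       latents_b: LatentMatrix | None = None,
                       corpus: list[MoleculeRecord] | None = None,
                       pair: tuple[str, str] = ("cosine", "cosine")):
    """Paired per-molecule similarity values for scatter plots.

    With two latent matrices (e.g. two temperatures) the pair compares
    the named latent metric across them; with one matrix it can pair
    cosine against euclidean or tanimoto (the latter needs the corpus).
    Returns a list of dict rows, one per non-query molecule.
    """
    if latents_b is not None and latents_a.ids != latents_b.ids:
        raise ValueError("latent matrices have mismatched ids")
    qa = latents_a.row(query_id)
    by_id = {r.id: r for r in corpus} if corpus else {}

    def value(metric: str, latents: LatentMatrix, mid: str) -> float:
        vec = latents.row(mid)
        qv = latents.row(query_id)
        if metric == "cosine":
            return _cosine(qv, vec)
        if metric == "euclidean":
            return float(np.linalg.norm(qv - vec))
        if metric == "tanimoto":
            return tanimoto(by_id[query_id].canonical_smiles,
                            by_id[mid].canonical_smiles)
        raise ValueError(f"unknown metric {metric!r}")

    rows = []
    for mid in latents_a.ids:
        if mid == query_id:
            continue
        rows.append({
            "id": mid,
            pair[0] + "_a": value(pair[0], latents_a, mid),
            pair[1] + "_b": value(pair[1], latents_b or latents_a, mid),
        })
    return rows


def dimension_population(latents: LatentMatrix,
                         epsilon: float = 0.0) -> DimensionPopulationSummary:
    """The three sparsity traces; an entry counts as nonzero iff |v| > eps."""
    nz = np.abs(latents.vectors) > epsilon
    per_row = nz.sum(axis=1)
    return DimensionPopulationSummary(
        always_nonzero=int(nz.all(axis=0).sum()),
        mean_nonzero=float(per_row.mean()),
        max_nonzero=int(per_row.max()),
        dimensionality=latents.vectors.shape[1])


def dimension_histogram(latents: LatentMatrix, corpus: list[MoleculeRecord],
                        dim: int, n_bins: int = 10,
                        representatives_per_bin: int = 3):
    """Equal-width histogram of one latent dimension with representatives.

    Returns (counts, edges, reps) where reps[b] lists up to m molecule
    ids whose value lies in bin b, nearest the bin center first.
    """
    d = latents.vectors.shape[1]
    if not 0 <= dim < d:
        raise ValueError(f"dimension {dim} outside [0, {d})")
    col = latents.vectors[:, dim]
    lo, hi = col.min(), col.max()
    if lo == hi:
        hi = lo + 1.0
    counts, edges = np.histogram(col, bins=n_bins, range=(lo, hi))
    idx = np.clip(np.digitize(col, edges) - 1, 0, n_bins - 1)
    reps: list[list[str]] = []
    for b in range(n_bins):
        center = 0.5 * (edges[b] + edges[b + 1])
        members = [(abs(col[i] - center), latents.ids[i])
                   for i in range(len(col)) if idx[i] == b]
        members.sort()
        reps.append([mid for _, mid in members[:representatives_per_bin]])
    return counts, edges, reps


def map_2d(latents: LatentMatrix, method: str, seed: int,
           corpus: list[MoleculeRecord] | None = None,
           out_png: str | Path | None = None, **params) -> np.ndarray:
    """2-D layout of the latent space via t-SNE or UMAP (seeded).

    Delegates to scikit-learn / umap-learn; optionally writes a scatter
    colored by class label.
    """
    n = latents.vectors.shape[0]
    if n < 5:
        raise ValueError("need at least 5 points for a 2-D map")
    if method == "tsne":
        from sklearn.manifold import TSNE
        perplexity = params.pop("perplexity", min(30.0, (n - 1) / 3))
        coords = TSNE(n_components=2, random_state=seed,
                      perplexity=perplexity, init="pca",
                      **params).fit_transform(latents.vectors)
    elif method == "umap":
        import umap
        n_neighbors = params.pop("n_neighbors", min(15, n - 1))
        coords = umap.UMAP(n_components=2, random_state=seed,
                           n_neighbors=n_neighbors,
                           **params).fit_transform(latents.vectors)
    else:
        raise ValueError(f"unknown method {method!r}")
    coords = np.asarray(coords, dtype=float)
    if out_png is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        labels = {r.id: r.label for r in (corpus or [])}
        fig, ax = plt.subplots(figsize=(6, 5))
        classes = sorted({labels.get(i, "other") for i in latents.ids})
        for cls in classes:
            pts = np.array([coords[j] for j, i in enumerate(latents.ids)
                            if labels.get(i, "other") == cls])
            ax.scatter(pts[:, 0], pts[:, 1], s=12, label=cls)
        ax.legend(fontsize=8)
        ax.set_xlabel(f"{method} 1")
        ax.set_ylabel(f"{method} 2")
        fig.savefig(out_png, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return coords
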