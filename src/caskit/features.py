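"""Cassette featurization: normalized best-bit-score matrices and dataset filters.

A cassette is an ordered set of Cas protein sequences.  Against a model
collection with families ``f_1 .. f_m`` it becomes a vector whose j-th entry
is the best normalized bit score any of family j's profiles attains on any
protein of the cassette, and exactly 0 when no profile detects it.  Stacking
cassettes gives the non-negative data matrix X in [0, 1]^(n x m) that the
classifiers and regressors consume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .profiles import ModelCollection, best_family_score

LABEL_COLUMN = "subtype"


@dataclass
class Cassette:
    """One CRISPR-Cas locus: proteins with optional family annotations."""

    cassette_id: str
    proteins: list[tuple]  # (protein_id, sequence) or (protein_id, sequence, family)
    subtype: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if not self.proteins:
            raise ValueError(f"cassette {self.cassette_id!r} has no proteins")
        ids = [p[0] for p in self.proteins]
        if len(ids) != len(set(ids)):
            raise ValueError(f"cassette {self.cassette_id!r} has duplicate protein ids")

    @property
    def sequences(self) -> list[str]:
        return [p[1] for p in self.proteins]

    @property
    def annotations(self) -> dict[str, str]:
        """protein_id -> annotated family, for annotated proteins only."""
        return {p[0]: p[2] for p in self.proteins if len(p) > 2 and p[2]}


@dataclass
class FeatureMatrix:
    """Labeled n x m matrix of normalized best bit scores.

    ``data`` is a DataFrame indexed by cassette id with one column per family;
    ``labels`` (optional) is a subtype Series aligned to the rows.
    """

    data: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("feature matrix entries must be non-negative")
        if self.labels is not None:
            self.labels = self.labels.reindex(self.data.index)
            if self.labels.isna().any():
                raise ValueError("labels, when present, must cover every row")

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        return self.data.shape[1]

    @property
    def families(self) -> list[str]:
        return list(self.data.columns)

    @property
    def X(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("matrix is unlabeled")
        return self.labels.to_numpy()

    def class_sizes(self) -> pd.Series:
        if self.labels is None:
            raise ValueError("matrix is unlabeled")
        return self.labels.value_counts()

    def select_rows(self, index) -> "FeatureMatrix":
        labels = self.labels.loc[index] if self.labels is not None else None
        return FeatureMatrix(self.data.loc[index].copy(), labels)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        if self.labels is not None:
            out[LABEL_COLUMN] = self.labels
        out.to_csv(path, index_label="cassette_id")

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="cassette_id")
        labels = None
        if LABEL_COLUMN in df.columns:
            labels = df.pop(LABEL_COLUMN).astype(str)
        return cls(df.astype(float), labels)


def build_feature_vector(cassette: Cassette, collection: ModelCollection) -> np.ndarray:
    """Best normalized family scores of one cassette, in collection column order."""
    if collection.n_families == 0:
        raise ValueError("model collection defines no families")
    seqs = cassette.sequences
    return np.array([best_family_score(collection, fam, seqs)
                     for fam in collection.families])


def assemble_matrix(cassettes: list[Cassette], collection: ModelCollection) -> FeatureMatrix:
    """Stack per-cassette feature vectors; labels copied from the cassettes."""
    if not cassettes:
        raise ValueError("no cassettes to assemble")
    ids = [c.cassette_id for c in cassettes]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate cassette ids")
    X = np.vstack([build_feature_vector(c, collection) for c in cassettes])
    data = pd.DataFrame(X, index=pd.Index(ids, name="cassette_id"),
                        columns=collection.families)
    labels = None
    if any(c.subtype is not None for c in cassettes):
        if not all(c.subtype is not None for c in cassettes):
            raise ValueError("either all cassettes carry a subtype label or none do")
        labels = pd.Series([c.subtype for c in cassettes], index=data.index)
    return FeatureMatrix(data, labels)


def filter_min_class_size(matrix: FeatureMatrix, min_size: int = 10
                          ) -> tuple[FeatureMatrix, list[str]]:
    """Drop rows of subtypes with fewer than ``min_size`` examples.

    Returns the filtered matrix and the list of dropped subtypes.  Classes
    must be large enough for every outer CV fold to contain each class, so
    this filter runs before any fold construction.
    """
    if matrix.labels is None:
        raise ValueError("class-size filtering needs a labeled matrix")
    sizes = matrix.class_sizes()
    dropped = sorted(sizes.index[sizes < min_size].tolist())
    keep = ~matrix.labels.isin(dropped)
    if not keep.any():
        raise ValueError(f"no class reaches the minimum size {min_size}")
    return matrix.select_rows(matrix.data.index[keep]), dropped


def split_complete_incomplete(cassettes: list[Cassette], collection: ModelCollection
                              ) -> tuple[list[Cassette], list[tuple[Cassette, list[str]]]]:
    """Separate cassettes whose every annotated family is detected from the rest.

    A cassette is *complete* when each family annotated on its proteins
    attains a positive score from the collection; incomplete cassettes form
    the independent test set, each tagged with its undetected families.
    Unannotated cassettes go to training with a warning.
    """
    training: list[Cassette] = []
    test: list[tuple[Cassette, list[str]]] = []
    for cassette in cassettes:
        annotated = sorted(set(cassette.annotations.values()))
        if not annotated:
            warnings.warn(f"cassette {cassette.cassette_id!r} has no family annotations; "
                          "routed to training", stacklevel=2)
            training.append(cassette)
            continue
        missing = [fam for fam in annotated
                   if fam not in collection.families
                   or best_family_score(collection, fam, cassette.sequences) <= 0]
        if missing:
            test.append((cassette, missing))
        else:
            training.append(cassette)
    return training, test


def completeness_summary(matrix: FeatureMatrix, prevalence_floor: float = 0.05
                         ) -> pd.DataFrame:
    """Per-subtype completeness over the subtype's prevalent families.

    A family belongs to a subtype's *support* when it is nonzero in at least
    ``prevalence_floor`` of that subtype's rows; completeness is the fraction
    of rows nonzero on the whole support.
    """
    if matrix.labels is None:
        raise ValueError("completeness summary needs a labeled matrix")
    rows = []
    for subtype, block in matrix.data.groupby(matrix.labels):
        prevalence = (block > 0).mean(axis=0)
        support = prevalence.index[prevalence >= prevalence_floor].tolist()
        complete = (block[support] > 0).all(axis=1).mean() if support else 0.0
        rows.append({"subtype": subtype, "n_cassettes": len(block),
                     "support_size": len(support),
                     "support": ";".join(support),
                     "completeness": float(complete)})
    return pd.DataFrame(rows).set_index("subtype")


def cassettes_from_fasta(path) -> list[Cassette]:
    """Read cassettes from FASTA with record ids ``cassetteID|proteinID[|family]``."""
    from Bio import SeqIO

    grouped: dict[str, list[tuple]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2:
            raise ValueError(f"record id {rec.id!r} is not 'cassetteID|proteinID[|family]'")
        cid, pid = parts[0], parts[1]
        family = parts[2] if len(parts) > 2 and parts[2] else None
        entry = (pid, str(rec.seq).upper(), family) if family else (pid, str(rec.seq).upper())
        grouped.setdefault(cid, []).append(entry)
    return [Cassette(cid, prots) for cid, prots in grouped.items()]
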