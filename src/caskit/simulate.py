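"""Synthetic fixtures with the statistical structure the method assumes.

Two generators cover the two halves of the pipeline:

* bit-score matrices with planted subtype signatures, correlated protein
  modules (a latent activity loading onto several families, the pattern
  behind association rules) and recorded missingness — a stand-in for the
  curated cassette datasets the real tool trains on;
* small protein families with planted subfamily structure (close within a
  subfamily, divergent between), exercising the clustering / profile
  construction stage with a known ground-truth partition.

Everything is reproducible bit-for-bit from the configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureMatrix
from .profiles import AMINO_ACIDS


@dataclass
class SimConfig:
    """Conditions for the planted bit-score matrix generator.

    Defaults plant one signature family per subtype at mean 0.85 against a
    zero background with noise sd 0.05 — clearly separated subtypes in a
    bounded score space, the regime in which the real classifiers operate.
    """

    k_subtypes: int = 3
    n_per_subtype: int = 100
    m_families: int = 12
    signature_map: dict[str, list[str]] | None = None
    module_map: dict[str, tuple[list[str], list[float]]] | None = None
    signature_mean: float = 0.85
    background_mean: float = 0.0
    noise_sd: float = 0.05
    background_presence: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for mean in (self.signature_mean, self.background_mean):
            if not 0 <= mean <= 1:
                raise ValueError("means must lie in [0, 1]")

    @property
    def families(self) -> list[str]:
        return [f"cas{j + 1}" for j in range(self.m_families)]

    @property
    def subtypes(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.k_subtypes)]

    def resolved_signature_map(self) -> dict[str, list[str]]:
        if self.signature_map is not None:
            sig = {k: list(v) for k, v in self.signature_map.items()}
        else:
            # one dedicated signature family per subtype: cas1 for S1, ...
            sig = {s: [self.families[i]] for i, s in enumerate(self.subtypes)}
        fams = set(self.families)
        for subtype, fam_list in sig.items():
            if not set(fam_list) <= fams:
                raise ValueError(f"signature families of {subtype} outside family list")
        shared = set.intersection(*(set(v) for v in sig.values())) if sig else set()
        if shared and len(sig) == self.k_subtypes and self.k_subtypes > 1:
            raise ValueError(f"families {sorted(shared)} are signatures of every subtype; "
                             "no subtype structure can be planted")
        return sig


@dataclass
class PlantedTruth:
    """Ground truth recorded alongside a generated matrix."""

    subtypes: pd.Series
    masked: dict[str, dict[str, float]]          # row -> {family: original value}
    module_coefficients: pd.DataFrame
    signature_map: dict[str, list[str]]


def _clip01(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def generate_bitscore_dataset(cfg: SimConfig) -> tuple[FeatureMatrix, PlantedTruth]:
    """Bit-score matrix with planted subtypes, modules and missingness.

    Per row: signature families ~ clipped N(signature_mean, noise_sd); module
    families = loading x latent U(0.3, 1) + noise; remaining families are 0
    with probability 1 - background_presence, else clipped N(0.1, noise_sd).
    Each nonzero entry is then masked to 0 with probability ``missing_rate``
    and recorded in the truth.
    """
    rng = np.random.default_rng(cfg.seed)
    sig_map = cfg.resolved_signature_map()
    families = cfg.families
    subtypes = cfg.subtypes
    n = cfg.k_subtypes * cfg.n_per_subtype
    labels = np.repeat(subtypes, cfg.n_per_subtype)
    ids = [f"C{i + 1:04d}" for i in range(n)]
    X = np.zeros((n, cfg.m_families))
    fam_idx = {f: j for j, f in enumerate(families)}

    module_map = cfg.module_map or {}
    module_families = {f for fams, _ in module_map.values() for f in fams}
    coeff = pd.DataFrame(0.0, index=list(module_map), columns=families)

    for i in range(n):
        row_sig = set(sig_map.get(labels[i], []))
        for fam in row_sig:
            X[i, fam_idx[fam]] = cfg.signature_mean + rng.normal(0, cfg.noise_sd)
        for mod, (fams, loadings) in module_map.items():
            latent = rng.uniform(0.3, 1.0)
            for fam, loading in zip(fams, loadings):
                X[i, fam_idx[fam]] = loading * latent + rng.normal(0, cfg.noise_sd)
        for fam in families:
            if fam in row_sig or fam in module_families:
                continue
            if rng.random() < cfg.background_presence:
                X[i, fam_idx[fam]] = max(cfg.background_mean, 0.1) + rng.normal(0, cfg.noise_sd)
    X = _clip01(X)

    for mod, (fams, loadings) in module_map.items():
        for fam, loading in zip(fams, loadings):
            coeff.loc[mod, fam] = loading

    masked: dict[str, dict[str, float]] = {}
    if cfg.missing_rate > 0:
        for i in range(n):
            for j in range(cfg.m_families):
                if X[i, j] > 0 and rng.random() < cfg.missing_rate:
                    masked.setdefault(ids[i], {})[families[j]] = float(X[i, j])
                    X[i, j] = 0.0

    data = pd.DataFrame(X, index=pd.Index(ids, name="cassette_id"), columns=families)
    label_series = pd.Series(labels, index=data.index)
    truth = PlantedTruth(subtypes=label_series, masked=masked,
                         module_coefficients=coeff, signature_map=sig_map)
    return FeatureMatrix(data, label_series), truth


def generate_protein_families(n_families: int = 2, subfamilies_per_family: int = 2,
                              seqs_per_subfamily: int = 4, within_rate: float = 0.1,
                              between_rate: float = 0.6, length: int = 120,
                              seed: int = 0
                              ) -> tuple[dict[str, dict[str, str]], dict[str, dict[str, list[str]]]]:
    """Protein families with planted subfamily structure, substitutions only.

    Per family one random ancestor; each subfamily is a variant of the
    ancestor at ``between_rate`` substituted positions, and each member a
    variant of its subfamily at ``within_rate``.  Returns ``family -> {id:
    seq}`` and the planted partition ``family -> {subfamily: [ids]}``.
    """
    if not (0 <= within_rate < 1 and 0 < between_rate < 1):
        raise ValueError("rates must lie in (0, 1)")
    if within_rate >= between_rate:
        raise ValueError("within_rate must be smaller than between_rate")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list(AMINO_ACIDS))

    def mutate(seq: np.ndarray, rate: float) -> np.ndarray:
        out = seq.copy()
        n_mut = int(round(rate * len(seq)))
        pos = rng.choice(len(seq), size=n_mut, replace=False)
        for p in pos:
            choices = alphabet[alphabet != out[p]]
            out[p] = rng.choice(choices)
        return out

    families: dict[str, dict[str, str]] = {}
    partition: dict[str, dict[str, list[str]]] = {}
    for fi in range(n_families):
        fam = f"fam{fi + 1}"
        ancestor = rng.choice(alphabet, size=length)
        families[fam] = {}
        partition[fam] = {}
        for si in range(subfamilies_per_family):
            sub = f"{fam}.sub{si + 1}"
            variant = mutate(ancestor, between_rate)
            partition[fam][sub] = []
            for mi in range(seqs_per_subfamily):
                sid = f"{sub}.m{mi + 1}"
                member = mutate(variant, within_rate)
                families[fam][sid] = "".join(member)
                partition[fam][sub].append(sid)
    return families, partition


def make_incomplete_cassettes(matrix: FeatureMatrix, n_missing_per_row: int = 1,
                              seed: int = 0
                              ) -> tuple[FeatureMatrix, dict[str, dict[str, float]]]:
    """Mask exactly ``n_missing_per_row`` nonzero entries per row, uniformly
    at random over the row's support; the mask record allows exact recovery."""
    rng = np.random.default_rng(seed)
    data = matrix.data.copy()
    mask: dict[str, dict[str, float]] = {}
    if n_missing_per_row == 0:
        return FeatureMatrix(data, matrix.labels), mask
    for rid, row in data.iterrows():
        support = row.index[row > 0].tolist()
        if len(support) < n_missing_per_row + 1:
            raise ValueError(f"row {rid!r}: only {len(support)} nonzero entries, cannot "
                             f"mask {n_missing_per_row} and keep evidence")
        chosen = rng.choice(support, size=n_missing_per_row, replace=False)
        mask[rid] = {fam: float(row[fam]) for fam in chosen}
        for fam in chosen:
            data.loc[rid, fam] = 0.0
    return FeatureMatrix(data, matrix.labels), mask


def default_module_config(seed: int = 0) -> SimConfig:
    """A ready-made configuration with one planted three-family module
    (loadings 0.8 / 0.6 / 0.5 on cas10..cas12), used for association-rule
    and imputation fixtures."""
    cfg = SimConfig(seed=seed)
    fams = cfg.families
    cfg.module_map = {"module1": ([fams[-3], fams[-2], fams[-1]], [0.8, 0.6, 0.5])}
    return cfg
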