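"""Profile models for Cas protein subfamilies and bit-score evaluation.

A :class:`ProfileModel` is a classic protein profile HMM: a chain of match
states with position-specific emission distributions over the 20 amino
acids, flanked by insert and delete states.  A sequence is scored in local
mode (free entry into any match state, free exit from any match state) and
the score is the log2 likelihood ratio of the best state path against a
background residue model — a bit score, as reported by hmmsearch.

Scores are made comparable across models by dividing by the model's own
consensus self-score and clipping to [0, 1]; the best normalized score of
any model of a family against any protein of a cassette is the cassette's
feature value for that family.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Robinson & Robinson amino-acid frequencies, the customary protein null model.
ROBINSON_BACKGROUND = np.array([
    0.0787945, 0.0151600, 0.0535222, 0.0668298, 0.0397062,
    0.0695071, 0.0229198, 0.0590092, 0.0594422, 0.0963728,
    0.0237718, 0.0414386, 0.0482904, 0.0395639, 0.0540978,
    0.0683364, 0.0540687, 0.0673417, 0.0114135, 0.0304133,
])

# Transition order used throughout (matches the HMMER3 file column order).
TRANS_ORDER = ("MM", "MI", "MD", "IM", "II", "DM", "DD")
MM, MI, MD, IM, II, DM, DD = range(7)


class ProfileFormatError(ValueError):
    """Raised when a HMMER3 stream or domtblout table is malformed."""


def family_from_name(name: str) -> str:
    """Resolve the Cas family from a model name of the form ``family__clusterN``.

    Names without the ``__`` separator are their own family.
    """
    return name.split("__")[0]


@dataclass
class ProfileModel:
    """One subfamily profile HMM.

    Parameters
    ----------
    name : str
        Model identifier; ``family__clusterN`` by convention.
    family : str
        Cas family the model detects (one feature-matrix column).
    match_emissions : (L, 20) array
        Per-match-state residue probabilities.
    insert_emissions : (L + 1, 20) array
        Per-node insert-state residue probabilities; row 0 is the begin node.
    transitions : (L + 1, 7) array
        Per-node outgoing probabilities in :data:`TRANS_ORDER`; row 0 is the
        begin node (unused by the local scorer, kept for format fidelity).
    background : (20,) array
        Null-model residue distribution.
    consensus : str
        Majority residue per match state; ``len(consensus) == L``.
    """

    name: str
    family: str
    match_emissions: np.ndarray
    insert_emissions: np.ndarray
    transitions: np.ndarray
    background: np.ndarray
    consensus: str
    _self_score: float | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        self.validate()

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def validate(self) -> None:
        L = self.length
        if L < 1:
            raise ValueError(f"model {self.name!r}: needs at least one match state")
        if self.match_emissions.shape != (L, 20):
            raise ValueError(f"model {self.name!r}: match_emissions must be (L, 20)")
        if self.insert_emissions.shape != (L + 1, 20):
            raise ValueError(f"model {self.name!r}: insert_emissions must be (L+1, 20)")
        if self.transitions.shape != (L + 1, 7):
            raise ValueError(f"model {self.name!r}: transitions must be (L+1, 7)")
        if len(self.consensus) != L:
            raise ValueError(f"model {self.name!r}: consensus length != model length")
        for label, block in (("match", self.match_emissions),
                             ("insert", self.insert_emissions),
                             ("background", self.background[None, :])):
            sums = block.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"model {self.name!r}: {label} emissions do not sum to 1")
        t = self.transitions
        for label, idx in (("M", [MM, MI, MD]), ("I", [IM, II]), ("D", [DM, DD])):
            sums = t[:, idx].sum(axis=1)
            # The last node has no onward I/D structure in some encodings; only
            # rows with any outgoing mass are constrained.
            live = sums > 0
            if not np.allclose(sums[live], 1.0, atol=1e-9):
                raise ValueError(f"model {self.name!r}: {label}-state transitions do not sum to 1")

    # -- scoring ---------------------------------------------------------

    def viterbi_bit_score(self, seq: str) -> float:
        """Best local-alignment bit score of ``seq`` against this profile.

        Residues outside the 20-letter alphabet emit at background frequency
        (log-odds 0).  Raises ``ValueError`` on the empty sequence.
        """
        return viterbi_bit_score(self, seq)

    def consensus_self_score(self) -> float:
        """Bit score of the model's own consensus; cached.

        An informative model scores its consensus strictly positively; a
        non-positive self-score marks the model unusable for normalization.
        """
        if self._self_score is None:
            self._self_score = viterbi_bit_score(self, self.consensus)
        return self._self_score

    @property
    def usable(self) -> bool:
        return self.consensus_self_score() > 0

    def normalized_score(self, seq: str) -> float:
        """Bit score divided by the consensus self-score, clipped to [0, 1]."""
        self_score = self.consensus_self_score()
        if self_score <= 0:
            raise ValueError(
                f"model {self.name!r} is uninformative (self-score {self_score:.3f} <= 0)")
        return float(np.clip(self.viterbi_bit_score(seq) / self_score, 0.0, 1.0))


def _encode(seq: str) -> np.ndarray:
    """Map residues to alphabet indices; unknown residues to -1 (background)."""
    return np.array([AA_INDEX.get(c, -1) for c in seq.upper()], dtype=int)


def viterbi_bit_score(model: ProfileModel, seq: str) -> float:
    """Local-mode Viterbi bit score (log2 best-path odds against background).

    Entry into any match state and exit from any match state are free; the
    path probability is the product of its transition probabilities and of
    emission/background odds of the residues it emits.
    """
    if len(seq) == 0:
        raise ValueError("cannot score an empty sequence")
    x = _encode(seq)
    L = model.length
    n = len(x)

    # A large-but-finite sentinel instead of -inf keeps the delete-state
    # running-max scan free of inf - inf artifacts.
    NEG = -1.0e30
    with np.errstate(divide="ignore"):
        lod_match = np.maximum(np.log2(model.match_emissions / model.background), NEG)
        lod_ins = np.maximum(np.log2(model.insert_emissions / model.background), NEG)
        lt = np.maximum(np.log2(model.transitions), NEG)

    # per-node transition vectors indexed by the *source* node (0-based node j
    # lives at row j); movement to node j+1 reads row j.
    t_mm, t_mi, t_md = lt[:, MM], lt[:, MI], lt[:, MD]
    t_im, t_ii = lt[:, IM], lt[:, II]
    t_dm, t_dd = lt[:, DM], lt[:, DD]

    # arrays over nodes 1..L at 0-based positions 0..L-1
    vm = np.full(L, NEG)
    vi = np.full(L, NEG)
    vd = np.full(L, NEG)
    # delete-chain cumulative costs: C[jj] = sum of D->D along nodes 1..jj
    cum_dd = np.concatenate(([0.0], np.cumsum(t_dd[1:L])))
    best = NEG
    for i in range(n):
        a = x[i]
        em = lod_match[:, a] if a >= 0 else np.zeros(L)
        ei = lod_ins[1:, a] if a >= 0 else np.zeros(L)
        stay = np.full(L, NEG)
        stay[1:] = np.maximum.reduce([vm[:-1] + t_mm[1:L],
                                      vi[:-1] + t_im[1:L],
                                      vd[:-1] + t_dm[1:L]])
        vm_new = em + np.maximum(0.0, stay)  # 0.0: free local entry
        vi_new = ei + np.maximum(vm + t_mi[1:], vi + t_ii[1:])
        # vd_new[jj] = max(vm_new[jj-1] + M->D, vd_new[jj-1] + D->D): a
        # max-plus prefix scan along the delete chain.
        vd_new = np.full(L, NEG)
        if L > 1:
            enter = vm_new[:-1] + t_md[1:L]          # entering D at node jj+1
            u = np.maximum.accumulate(enter - cum_dd[1:])
            vd_new[1:] = u + cum_dd[1:]
        vm, vi, vd = vm_new, vi_new, vd_new
        best = max(best, float(vm.max()))  # free local exit from any match
    return float(best)


def consensus_self_score(model: ProfileModel) -> float:
    return model.consensus_self_score()


@dataclass
class Hit:
    """One profile-vs-sequence hit (a domtblout row or an in-house evaluation)."""

    model_name: str
    family: str
    sequence_id: str
    raw_bits: float
    normalized_score: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.raw_bits):
            raise ValueError(f"hit {self.model_name}/{self.sequence_id}: non-finite bit score")
        if self.normalized_score is not None and not 0.0 <= self.normalized_score <= 1.0:
            raise ValueError("normalized_score must lie in [0, 1]")


@dataclass
class ModelCollection:
    """A named set of profiles grouped by Cas family; defines the feature space."""

    collection_id: str
    models: dict[str, list[ProfileModel]]
    families: list[str]

    def __post_init__(self) -> None:
        for fam in self.models:
            if fam not in self.families:
                raise ValueError(f"family {fam!r} has models but is not listed in families")
        names = [m.name for fam in self.models for m in self.models[fam]]
        if len(names) != len(set(names)):
            raise ValueError("model names must be unique within a collection")

    @property
    def n_families(self) -> int:
        return len(self.families)

    def __len__(self) -> int:
        return sum(len(v) for v in self.models.values())

    def all_models(self) -> list[ProfileModel]:
        return [m for fam in self.families for m in self.models.get(fam, [])]

    @classmethod
    def from_models(cls, collection_id: str, models: list[ProfileModel],
                    families: list[str] | None = None) -> "ModelCollection":
        by_family: dict[str, list[ProfileModel]] = {}
        for m in models:
            by_family.setdefault(m.family, []).append(m)
        if families is None:
            families = sorted(by_family)
        return cls(collection_id, by_family, list(families))


def best_family_score(collection: ModelCollection, family: str,
                      seqs: list[str]) -> float:
    """Best normalized bit score of any of ``family``'s models on any sequence.

    Returns 0.0 when no model/sequence evaluation is positive ("zero
    otherwise").  Uninformative models (non-positive self-score) are skipped.
    """
    if family not in collection.families:
        raise KeyError(f"family {family!r} not in collection {collection.collection_id!r}")
    best = 0.0
    for model in collection.models.get(family, []):
        if not model.usable:
            continue
        for seq in seqs:
            best = max(best, model.normalized_score(seq))
    return best


# -- HMMER3 ASCII I/O ----------------------------------------------------


def _prob_from_field(tok: str) -> float:
    """HMMER3 stores -ln(p); '*' encodes probability zero."""
    return 0.0 if tok == "*" else math.exp(-float(tok))


def _field_from_prob(p: float) -> str:
    return "*".rjust(8) if p <= 0 else f"{-math.log(p):8.5f}"


def read_hmmer3(stream) -> list[ProfileModel]:
    """Parse one or more profiles from a HMMER3 ASCII stream.

    Only the amino alphabet is supported.  The node-0 insert emission line is
    taken as the background distribution (the HMMER convention of inserts
    emitting at null frequencies).  Negative-log fields become probabilities;
    ``*`` parses to probability 0.
    """
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    models: list[ProfileModel] = []
    i = 0
    nlines = len(lines)
    while i < nlines:
        while i < nlines and not lines[i].strip():
            i += 1
        if i >= nlines:
            break
        if not lines[i].startswith("HMMER3"):
            raise ProfileFormatError(f"line {i + 1}: expected HMMER3 header, got {lines[i]!r}")
        i += 1
        name = None
        leng = None
        alph = None
        while i < nlines and not lines[i].startswith("HMM "):
            key = lines[i][:6].strip()
            val = lines[i][6:].strip()
            if key == "NAME":
                name = val
            elif key == "LENG":
                leng = int(val)
            elif key == "ALPH":
                alph = val.lower()
            i += 1
        if i >= nlines:
            raise ProfileFormatError("truncated record: no HMM line")
        if name is None or leng is None:
            raise ProfileFormatError(f"line {i + 1}: record missing NAME or LENG")
        if alph != "amino":
            raise ProfileFormatError(f"line {i + 1}: unsupported alphabet {alph!r}")
        i += 2  # HMM residue-order line + transition-order line
        if i < nlines and lines[i].lstrip().startswith("COMPO"):
            i += 1
        # node 0: insert emissions (background) + transitions
        try:
            bg = np.array([_prob_from_field(t) for t in lines[i].split()])
            t0 = [_prob_from_field(t) for t in lines[i + 1].split()]
        except (IndexError, ValueError) as exc:
            raise ProfileFormatError(f"line {i + 1}: malformed node-0 block: {exc}") from None
        if bg.size != 20 or len(t0) != 7:
            raise ProfileFormatError(f"line {i + 1}: node-0 block has wrong arity")
        i += 2
        match_em = np.zeros((leng, 20))
        insert_em = np.zeros((leng + 1, 20))
        trans = np.zeros((leng + 1, 7))
        insert_em[0] = bg
        trans[0] = t0
        consensus = []
        for k in range(1, leng + 1):
            try:
                mtoks = lines[i].split()
                itoks = lines[i + 1].split()
                ttoks = lines[i + 2].split()
            except IndexError:
                raise ProfileFormatError(
                    f"record {name!r}: truncated at node {k}") from None
            if len(mtoks) < 21 or int(mtoks[0]) != k:
                raise ProfileFormatError(f"line {i + 1}: bad match line for node {k}")
            if len(itoks) != 20 or len(ttoks) != 7:
                raise ProfileFormatError(f"line {i + 2}: bad insert/transition line at node {k}")
            match_em[k - 1] = [_prob_from_field(t) for t in mtoks[1:21]]
            cons = mtoks[22] if len(mtoks) >= 23 and re.fullmatch(r"[A-Za-z-]", mtoks[22]) else None
            consensus.append(cons.upper() if cons else AMINO_ACIDS[int(np.argmax(match_em[k - 1]))])
            insert_em[k] = [_prob_from_field(t) for t in itoks]
            trans[k] = [_prob_from_field(t) for t in ttoks]
            i += 3
        if i >= nlines or lines[i].strip() != "//":
            raise ProfileFormatError(f"record {name!r}: missing '//' terminator")
        i += 1
        models.append(ProfileModel(
            name=name, family=family_from_name(name),
            match_emissions=match_em, insert_emissions=insert_em,
            transitions=trans, background=bg, consensus="".join(consensus)))
    if not models:
        raise ProfileFormatError("stream contains no HMMER3 records")
    return models


def write_hmmer3(models: list[ProfileModel] | ProfileModel, stream) -> None:
    """Write profiles in HMMER3/f ASCII (readable back by :func:`read_hmmer3`)."""
    if isinstance(models, ProfileModel):
        models = [models]

    def emit_row(values, out):
        out.append("  ".join(_field_from_prob(p) for p in values))

    chunks: list[str] = []
    for m in models:
        L = m.length
        chunks.append("HMMER3/f [caskit | profile writer]")
        chunks.append(f"NAME  {m.name}")
        chunks.append(f"LENG  {L}")
        chunks.append("ALPH  amino")
        chunks.append("RF    no")
        chunks.append("MM    no")
        chunks.append("CONS  yes")
        chunks.append("CS    no")
        chunks.append("MAP   yes")
        chunks.append("HMM          " + "        ".join(AMINO_ACIDS))
        chunks.append("            " + "     ".join(f"{t[0].lower()}->{t[1].lower()}"
                                                    for t in TRANS_ORDER))
        compo = m.match_emissions.mean(axis=0)
        row: list[str] = []
        emit_row(compo, row)
        chunks.append("  COMPO   " + row[0])
        row = []
        emit_row(m.insert_emissions[0], row)
        chunks.append("          " + row[0])
        row = []
        emit_row(m.transitions[0], row)
        chunks.append("          " + row[0])
        for k in range(1, L + 1):
            row = []
            emit_row(m.match_emissions[k - 1], row)
            chunks.append(f"{k:>7d}   " + row[0] + f"{k:>7d} {m.consensus[k - 1].lower()} - - -")
            row = []
            emit_row(m.insert_emissions[k], row)
            chunks.append("          " + row[0])
            row = []
            emit_row(m.transitions[k], row)
            chunks.append("          " + row[0])
        chunks.append("//")
    stream.write("\n".join(chunks) + "\n")


# -- hmmsearch domtblout adapter ----------------------------------------

#: minimum column count of a domtblout data row
_DOMTBL_MIN_COLS = 22
_FULL_SEQ_SCORE_COL = 7
_BEST_DOMAIN_SCORE_COL = 13


def parse_domtblout(stream, score: str = "full_sequence") -> list[Hit]:
    """Read hits from an ``hmmsearch --domtblout`` table.

    ``score`` selects the bit-score column: ``"full_sequence"`` (default) or
    ``"best_domain"``.  Model family is resolved from the query-name prefix
    (``family__clusterN``).  Normalization is left to the caller.
    """
    col = {"full_sequence": _FULL_SEQ_SCORE_COL,
           "best_domain": _BEST_DOMAIN_SCORE_COL}.get(score)
    if col is None:
        raise ValueError(f"unknown score column selector {score!r}")
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    hits: list[Hit] = []
    for lineno, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith("#"):
            continue
        toks = line.split()
        if len(toks) < _DOMTBL_MIN_COLS:
            raise ProfileFormatError(
                f"line {lineno}: domtblout row has {len(toks)} columns, "
                f"expected >= {_DOMTBL_MIN_COLS}")
        query = toks[3]
        hits.append(Hit(model_name=query, family=family_from_name(query),
                        sequence_id=toks[0], raw_bits=float(toks[col])))
    return hits
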