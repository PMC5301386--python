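"""Energy-like sequence-window statistical potentials.

For a binary per-residue state u (epitope/non-epitope, or exposed/buried) the
potentials quantify how the amino-acid types found in a small sequence
interval around a residue shift the odds of its state, in inverse-Boltzmann
form.  With F(.) relative frequencies counted on a training corpus,

    dw1(u, s)     = -RT ln [ F(u, s) / (F(u) F(s)) ]
    dw2(u, s, s') = -RT ln [ F(u, s, s') / (F(u) F(s, s')) ]

where s (and the unordered pair {s, s'}) ranges over the types at positions j
(j < k) inside the interval I = 2w + 1 centred on the residue, the central
position included.  Frequencies are counted over *incidences* -- one count
per (central residue, window position) event for the singlet tables and one
per (central residue, unordered position pair) event for the pair tables --
so all marginals of a table share a common total and sum consistently.

Sparse counts are shrunk toward an odds ratio of 1 with weight sigma
(default 10):

    r -> (sigma + n r) / (sigma + n)

with n the incidence count of the type (or type pair), so potentials of
rarely observed types tend to 0.

The per-residue score sums the table entries over the interval,

    dW(u) = sum_j dw1(u, s_j) + sum_{j<k} dw2(u, s_j, s_k),

truncating the interval at chain termini; neighbours of non-standard type
contribute nothing.  dW(u=epitope) with I = 7 is the "energy-like" epitope
feature; the same machinery on exposed/buried labels gives the accessibility
feature.  RT is 0.593 kcal/mol (room temperature, natural log); any positive
constant would only rescale the scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .seqdata import (
    AA_INDEX,
    AMINO_ACIDS,
    Corpus,
    EPITOPE_STATES,
    EXPOSURE_STATES,
)

#: kcal/mol at ~298 K with natural logarithms.
RT = 0.593

N_AA = len(AMINO_ACIDS)


class TrainingError(ValueError):
    """The corpus cannot support the requested model (e.g. empty state)."""


def encode_sequence(sequence: str) -> np.ndarray:
    """Integer-encode a sequence; non-standard residues become -1."""
    return np.array([AA_INDEX.get(ch, -1) for ch in sequence], dtype=np.int64)


@dataclass
class PotentialScore:
    """Energy-like score of one residue for one state: dW = dW1 + dW2."""

    dw1: float
    dw2: float

    @property
    def dw(self) -> float:
        return self.dw1 + self.dw2


@dataclass
class FrequencyModel:
    """Incidence counts and derived potentials for one binary state task.

    ``counts_single[u, s]`` counts (central residue of state u, window
    position of type s) incidences; ``counts_pair[u, a, b]`` (a <= b)
    counts (state u, unordered window type pair {a, b}) incidences.
    Marginals are derived from these tables, never stored separately.
    """

    task: str
    states: tuple[str, str]
    interval: int
    sigma: float
    rt: float = RT
    counts_single: np.ndarray = field(
        default_factory=lambda: np.zeros((2, N_AA), dtype=np.int64)
    )
    counts_pair: np.ndarray = field(
        default_factory=lambda: np.zeros((2, N_AA, N_AA), dtype=np.int64)
    )

    # cached dense tables, built lazily
    _dw1: np.ndarray | None = field(default=None, repr=False, compare=False)
    _dw2: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def w(self) -> int:
        return (self.interval - 1) // 2

    def state_index(self, u: str) -> int:
        try:
            return self.states.index(u)
        except ValueError:
            raise KeyError(f"state {u!r} not in {self.states}") from None

    # -- frequency accessors ------------------------------------------------

    @property
    def n_single(self) -> int:
        return int(self.counts_single.sum())

    @property
    def n_pair(self) -> int:
        return int(self.counts_pair.sum())

    def freq_state(self, u: str) -> float:
        return self.counts_single[self.state_index(u)].sum() / self.n_single

    def freq_type(self, s: str) -> float:
        return self.counts_single[:, AA_INDEX[s]].sum() / self.n_single

    def freq_state_type(self, u: str, s: str) -> float:
        return self.counts_single[self.state_index(u), AA_INDEX[s]] / self.n_single

    # -- corrected ratios and potentials ------------------------------------

    def _tables(self) -> tuple[np.ndarray, np.ndarray]:
        if self._dw1 is None:
            self._dw1, self._dw2 = _build_tables(self)
        return self._dw1, self._dw2

    def delta_w1(self, u: str, s: str) -> float:
        return float(self._tables()[0][self.state_index(u), AA_INDEX[s]])

    def delta_w2(self, u: str, s: str, s2: str) -> float:
        a, b = sorted((AA_INDEX[s], AA_INDEX[s2]))
        return float(self._tables()[1][self.state_index(u), a, b])

    def _invalidate(self) -> None:
        self._dw1 = self._dw2 = None


def _corrected(ratio_num: np.ndarray, n_type: np.ndarray, sigma: float) -> np.ndarray:
    """Shrink raw frequency ratios toward 1: (sigma + n r) / (sigma + n).

    ``ratio_num`` holds n * r (finite even when n = 0, where the corrected
    ratio is exactly 1).
    """
    return (sigma + ratio_num) / (sigma + n_type)


def corrected_ratio(
    model: FrequencyModel, kind: str, u: str, s: str, s2: str | None = None
) -> float:
    """Sparse-data-corrected frequency ratio for one table cell.

    ``kind`` is ``"single"`` or ``"pair"``.  Returns exactly 1 for a type
    (pair) never observed in the training windows, and approaches the raw
    ratio F(u,s)/(F(u)F(s)) as the count grows.
    """
    ui = model.state_index(u)
    if kind == "single":
        total = model.n_single
        n_u = model.counts_single[ui].sum()
        n_s = model.counts_single[:, AA_INDEX[s]].sum()
        n_us = model.counts_single[ui, AA_INDEX[s]]
    elif kind == "pair":
        if s2 is None:
            raise ValueError("pair kind requires two types")
        a, b = sorted((AA_INDEX[s], AA_INDEX[s2]))
        total = model.n_pair
        n_u = model.counts_pair[ui].sum()
        n_s = model.counts_pair[:, a, b].sum()
        n_us = model.counts_pair[ui, a, b]
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if n_s == 0 or n_u == 0:
        return 1.0
    raw_num = n_s * (n_us * total / (n_u * n_s))  # n * r
    return float((model.sigma + raw_num) / (model.sigma + n_s))


def _build_tables(model: FrequencyModel) -> tuple[np.ndarray, np.ndarray]:
    """Dense dw1 (2 x 20) and symmetric dw2 (2 x 20 x 20) tables."""
    sigma, rt = model.sigma, model.rt

    cs = model.counts_single.astype(float)
    total1 = cs.sum()
    n_u1 = cs.sum(axis=1, keepdims=True)  # (2,1)
    n_s1 = cs.sum(axis=0, keepdims=True)  # (1,20)
    with np.errstate(divide="ignore", invalid="ignore"):
        r_num1 = np.where(n_u1 > 0, cs * total1 / n_u1, 0.0)  # n(s) * r
    dw1 = -rt * np.log(_corrected(r_num1, n_s1, sigma))

    cp = model.counts_pair.astype(float)
    total2 = cp.sum()
    n_u2 = cp.sum(axis=(1, 2)).reshape(2, 1, 1)
    n_ss = cp.sum(axis=0, keepdims=True)
    if total2 > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            r_num2 = np.where(n_u2 > 0, cp * total2 / n_u2, 0.0)
        dw2 = -rt * np.log(_corrected(r_num2, n_ss, sigma))
    else:
        dw2 = np.zeros_like(cp)
    # mirror the canonical upper triangle so lookups need no sorting
    iu = np.triu_indices(N_AA)
    for ui in range(2):
        m = dw2[ui]
        m.T[iu] = m[iu]
    return dw1, dw2


def _labels_for_task(record, task: str) -> str:
    if task == "epitope":
        return record.labels
    if task == "exposure":
        if not record.exposure:
            return "U" * len(record)
        return record.exposure
    raise ValueError(f"unknown state task {task!r}")


def states_for_task(task: str) -> tuple[str, str]:
    return EPITOPE_STATES if task == "epitope" else EXPOSURE_STATES


def train_frequency_model(
    corpus: Corpus,
    state_task: str = "epitope",
    interval: int = 7,
    sigma: float = 10.0,
    rt: float = RT,
) -> FrequencyModel:
    """Count state/type incidences over sequence windows of size ``interval``.

    One pass over every residue with a defined state and standard type: each
    in-chain window position of standard type adds one singlet incidence, and
    each unordered pair of such positions adds one pair incidence.
    ``interval`` must be odd and between 1 and 17.
    """
    if interval % 2 != 1 or not (1 <= interval <= 17):
        raise ValueError(f"interval must be odd and in 1..17, got {interval}")
    states = states_for_task(state_task)
    model = FrequencyModel(
        task=state_task, states=states, interval=interval, sigma=sigma, rt=rt
    )
    w = model.w
    state_codes = {states[0]: 0, states[1]: 1}
    for rec in corpus:
        enc = encode_sequence(rec.sequence)
        lab = _labels_for_task(rec, state_task)
        L = len(enc)
        u_idx = np.array([state_codes.get(c, -1) for c in lab], dtype=np.int64)
        central = (u_idx >= 0) & (enc >= 0)
        centers = np.nonzero(central)[0]
        if centers.size == 0:
            continue
        offsets = range(-w, w + 1)
        # in-chain standard-type neighbours per centre, per offset
        for d in offsets:
            j = centers + d
            ok = (j >= 0) & (j < L)
            ok[ok] &= enc[j[ok]] >= 0
            ci = centers[ok]
            np.add.at(model.counts_single, (u_idx[ci], enc[ci + d]), 1)
        for di, d1 in enumerate(offsets):
            for d2 in list(offsets)[di + 1 :]:
                j, k = centers + d1, centers + d2
                ok = (j >= 0) & (k < L)
                ok[ok] &= (enc[j[ok]] >= 0) & (enc[k[ok]] >= 0)
                ci = centers[ok]
                if ci.size == 0:
                    continue
                a = enc[ci + d1]
                b = enc[ci + d2]
                lo, hi = np.minimum(a, b), np.maximum(a, b)
                np.add.at(model.counts_pair, (u_idx[ci], lo, hi), 1)
    per_state = model.counts_single.sum(axis=1)
    if (per_state == 0).any():
        empty = [states[i] for i in range(2) if per_state[i] == 0]
        raise TrainingError(
            f"no labeled residues in state(s) {empty} for task {state_task!r}"
        )
    return model


def score_residue(
    model: FrequencyModel, sequence: str, i: int, u: str
) -> PotentialScore:
    """Energy-like score of residue ``i`` for state ``u``.

    Sums the singlet table over every in-chain standard-type position within
    w of i, and the pair table over every unordered pair of such positions;
    the window truncates at the chain termini.
    """
    if not 0 <= i < len(sequence):
        raise IndexError(f"residue index {i} outside sequence")
    dw1t, dw2t = model._tables()
    ui = model.state_index(u)
    enc = encode_sequence(sequence)
    w = model.w
    lo, hi = max(0, i - w), min(len(sequence), i + w + 1)
    window = [j for j in range(lo, hi) if enc[j] >= 0]
    s1 = sum(dw1t[ui, enc[j]] for j in window)
    s2 = sum(
        dw2t[ui, enc[j], enc[k]]
        for a, j in enumerate(window)
        for k in window[a + 1 :]
    )
    return PotentialScore(dw1=float(s1), dw2=float(s2))


def scan_sequence(
    model: FrequencyModel, sequence: str, u: str, components: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Vectorized dW over every residue of a sequence.

    Returns the per-residue dW vector, or the (dW1, dW2) component vectors
    when ``components`` is true.
    """
    dw1t, dw2t = model._tables()
    ui = model.state_index(u)
    enc = encode_sequence(sequence)
    L = enc.size
    w = model.w
    dW1 = np.zeros(L)
    dW2 = np.zeros(L)
    idx = np.arange(L)
    offsets = range(-w, w + 1)
    for d in offsets:
        j = idx + d
        ok = (j >= 0) & (j < L)
        ok[ok] &= enc[j[ok]] >= 0
        dW1[ok] += dw1t[ui, enc[idx[ok] + d]]
    for a, d1 in enumerate(offsets):
        for d2 in list(offsets)[a + 1 :]:
            j, k = idx + d1, idx + d2
            ok = (j >= 0) & (k < L)
            ok[ok] &= (enc[j[ok]] >= 0) & (enc[k[ok]] >= 0)
            sel = idx[ok]
            dW2[ok] += dw2t[ui, enc[sel + d1], enc[sel + d2]]
    if components:
        return dW1, dW2
    return dW1 + dW2


# ---------------------------------------------------------------------------
# Serialization: TSV of (kind, state, type, type2, count, delta_w)


def model_to_tsv(model: FrequencyModel, path: str | Path) -> None:
    """Write the count tables and derived potentials as inspectable TSV."""
    rows = []
    for ui, u in enumerate(model.states):
        for si, s in enumerate(AMINO_ACIDS):
            rows.append(
                (
                    "single",
                    u,
                    s,
                    ".",
                    int(model.counts_single[ui, si]),
                    model.freq_state_type(u, s) if model.n_single else np.nan,
                    model.delta_w1(u, s),
                )
            )
    for ui, u in enumerate(model.states):
        for a in range(N_AA):
            for b in range(a, N_AA):
                rows.append(
                    (
                        "pair",
                        u,
                        AMINO_ACIDS[a],
                        AMINO_ACIDS[b],
                        int(model.counts_pair[ui, a, b]),
                        model.counts_pair[ui, a, b] / model.n_pair
                        if model.n_pair
                        else np.nan,
                        model.delta_w2(u, AMINO_ACIDS[a], AMINO_ACIDS[b]),
                    )
                )
    df = pd.DataFrame(
        rows,
        columns=["kind", "state", "type", "type2", "count", "frequency", "delta_w"],
    )
    with open(path, "w") as fh:
        fh.write(
            f"# task={model.task} states={''.join(model.states)} "
            f"interval={model.interval} sigma={model.sigma!r} rt={model.rt!r}\n"
        )
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def model_from_tsv(path: str | Path) -> FrequencyModel:
    """Rebuild a model from its TSV dump; counts round-trip exactly."""
    with open(path) as fh:
        header = fh.readline()
    meta = dict(
        item.split("=", 1) for item in header.lstrip("# ").strip().split(" ")
    )
    states = (meta["states"][0], meta["states"][1])
    model = FrequencyModel(
        task=meta["task"],
        states=states,
        interval=int(meta["interval"]),
        sigma=float(meta["sigma"]),
        rt=float(meta["rt"]),
    )
    df = pd.read_csv(path, sep="\t", comment="#")
    for _, row in df.iterrows():
        ui = model.state_index(row["state"])
        if row["kind"] == "single":
            model.counts_single[ui, AA_INDEX[row["type"]]] = int(row["count"])
        else:
            a, b = sorted((AA_INDEX[row["type"]], AA_INDEX[row["type2"]]))
            model.counts_pair[ui, a, b] = int(row["count"])
    return model
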