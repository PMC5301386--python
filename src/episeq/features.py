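"""Per-residue feature table and its windowed expansion.

Thirteen per-residue features feed the classifier.  Five are computed here
from the training corpus and the sequence itself:

* F1 -- ratio of each amino-acid type's frequency in epitopes over its
  frequency in the remaining (non-epitope) antigen *surface*;
* F2 -- the same ratio against the whole remaining antigen;
* F3 -- Hopp-Woods hydrophilicity;
* F9 -- energy-like epitope/non-epitope potential score (interval I);
* F11 -- energy-like exposed/buried potential score (interval I).

The remaining features (secondary structure, flexibility, disorder,
solubility, conservation, predicted accessibility) come from external
per-residue predictors and are ingested as named numeric columns, never
recomputed.  Missing external cells are imputed with the training-set column
mean.

For prediction, each residue's row is the concatenation of the feature
vectors of the W window positions centred on it (W = 9 by default); window
positions falling off the chain are filled with the training column means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import potentials
from .seqdata import AMINO_ACIDS, AA_INDEX, Corpus
from .potentials import FrequencyModel, scan_sequence, train_frequency_model

#: Hopp & Woods (1981) hydrophilicity scale; charged residues (D, E, K, R)
#: share the maximum of +3.0, tryptophan has the minimum of -3.4.
HOPP_WOODS = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}
_HW_VALUES = np.array([HOPP_WOODS[aa] for aa in AMINO_ACIDS])
_HW_MEAN = float(_HW_VALUES.mean())


class ConfigurationError(ValueError):
    """The feature registry cannot be satisfied by the given corpus."""


@dataclass(frozen=True)
class FeatureDef:
    """One feature: where its values come from and which columns it owns.

    ``source`` is ``computed`` (F1/F2/F3), ``potential`` (F9/F11) or
    ``external``; external features may contribute several columns (e.g.
    three secondary-structure propensities), named after the annotation
    columns they read.
    """

    name: str
    source: str
    columns: tuple[str, ...] = ()

    def __post_init__(self):
        if self.source not in ("computed", "potential", "external"):
            raise ConfigurationError(f"unknown feature source {self.source!r}")
        if not self.columns:
            object.__setattr__(self, "columns", (self.name,))

    @property
    def arity(self) -> int:
        return len(self.columns)


#: Features computable from sequence + labels alone (reduced mode).
COMPUTED_FEATURES = (
    FeatureDef("F1", "computed"),
    FeatureDef("F2", "computed"),
    FeatureDef("F3", "computed"),
    FeatureDef("F9", "potential"),
    FeatureDef("F11", "potential"),
)


@dataclass
class FeatureRegistry:
    """Ordered set of feature definitions with unique names."""

    features: tuple[FeatureDef, ...]

    def __post_init__(self):
        names = [f.name for f in self.features]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate feature names in {names}")
        cols = [c for f in self.features for c in f.columns]
        if len(set(cols)) != len(cols):
            raise ConfigurationError("feature column names collide")

    @classmethod
    def reduced(cls) -> "FeatureRegistry":
        """F1, F2, F3, F9, F11 -- no external predictors needed."""
        return cls(COMPUTED_FEATURES)

    @classmethod
    def with_external(cls, external: dict[str, tuple[str, ...]]) -> "FeatureRegistry":
        """Reduced registry plus external features {name: column names}."""
        ext = tuple(
            FeatureDef(name, "external", tuple(cols) if cols else (name,))
            for name, cols in external.items()
        )
        return cls(COMPUTED_FEATURES + ext)

    def subset(self, names: list[str]) -> "FeatureRegistry":
        by_name = {f.name: f for f in self.features}
        missing = [n for n in names if n not in by_name]
        if missing:
            raise ConfigurationError(f"unknown features {missing}")
        return FeatureRegistry(tuple(by_name[n] for n in names))

    @property
    def names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def column_names(self) -> list[str]:
        return [c for f in self.features for c in f.columns]

    def __iter__(self):
        return iter(self.features)

    def __len__(self):
        return len(self.features)


@dataclass
class CompositionRatios:
    """Per-type epitope composition ratios (features F1 and F2).

    Frequencies are smoothed with one pseudo-count per type in every
    population, so ratios are strictly positive even for types unseen in
    epitopes.  Residues of unknown type take the mean ratio.
    """

    ratio_surface: np.ndarray  # (20,) epitope freq / exposed non-epitope freq
    ratio_antigen: np.ndarray  # (20,) epitope freq / non-epitope freq

    def lookup(self, sequence: str, which: str) -> np.ndarray:
        table = self.ratio_surface if which == "surface" else self.ratio_antigen
        default = float(table.mean())
        return np.array(
            [table[AA_INDEX[c]] if c in AA_INDEX else default for c in sequence]
        )


def _smoothed_freqs(counts: np.ndarray) -> np.ndarray:
    counts = counts + 1.0  # one pseudo-count per type
    return counts / counts.sum()


def fit_composition_ratios(corpus: Corpus) -> CompositionRatios:
    """Estimate F1/F2 ratio tables from a labeled corpus.

    F1 compares epitope composition with the exposed non-epitope residues,
    F2 with all non-epitope residues.  Requires epitope and exposure labels.
    """
    epi = np.zeros(20)
    nonepi = np.zeros(20)
    surface_nonepi = np.zeros(20)
    for rec in corpus:
        for i, aa in enumerate(rec.sequence):
            si = AA_INDEX.get(aa)
            if si is None:
                continue
            lab = rec.labels[i]
            if lab == "E":
                epi[si] += 1
            elif lab == "N":
                nonepi[si] += 1
                if rec.exposure and rec.exposure[i] == "E":
                    surface_nonepi[si] += 1
    if epi.sum() == 0:
        raise potentials.TrainingError("corpus contains no epitope residues")
    f_epi = _smoothed_freqs(epi)
    return CompositionRatios(
        ratio_surface=f_epi / _smoothed_freqs(surface_nonepi),
        ratio_antigen=f_epi / _smoothed_freqs(nonepi),
    )


def hydrophilicity(sequence: str) -> np.ndarray:
    """Hopp-Woods hydrophilicity per residue; unknown types take the mean."""
    return np.array(
        [HOPP_WOODS.get(c, _HW_MEAN) for c in sequence], dtype=float
    )


def assemble_residue_features(
    corpus: Corpus,
    registry: FeatureRegistry,
    ratios: CompositionRatios | None = None,
    pot_epitope: FrequencyModel | None = None,
    pot_exposure: FrequencyModel | None = None,
    impute_means: pd.Series | None = None,
) -> pd.DataFrame:
    """One row per residue, indexed by (record id, 0-based position).

    Computed and potential features require their fitted helpers; external
    columns are read from the records' attached annotations, with missing
    cells imputed from ``impute_means`` (or the corpus column mean when no
    training means are supplied).  An external column absent from the whole
    corpus raises :class:`ConfigurationError`.
    """
    frames = []
    for rec in corpus:
        n = len(rec)
        cols: dict[str, np.ndarray] = {}
        for feat in registry:
            if feat.name == "F1":
                cols["F1"] = ratios.lookup(rec.sequence, "surface")
            elif feat.name == "F2":
                cols["F2"] = ratios.lookup(rec.sequence, "antigen")
            elif feat.name == "F3":
                cols["F3"] = hydrophilicity(rec.sequence)
            elif feat.source == "potential":
                model = pot_epitope if feat.name == "F9" else pot_exposure
                if model is None:
                    raise ConfigurationError(
                        f"feature {feat.name} needs a trained potential model"
                    )
                cols[feat.name] = scan_sequence(model, rec.sequence, "E")
            elif feat.source == "computed":
                raise ConfigurationError(f"unknown computed feature {feat.name}")
            else:
                for cname in feat.columns:
                    col = rec.extra_features.get(cname)
                    cols[cname] = (
                        np.full(n, np.nan) if col is None else col.astype(float)
                    )
        idx = pd.MultiIndex.from_arrays(
            [[rec.id] * n, np.arange(n)], names=["record_id", "position"]
        )
        frames.append(pd.DataFrame(cols, index=idx))
    table = pd.concat(frames)
    table = table[registry.column_names]

    all_missing = [c for c in table.columns if table[c].isna().all()]
    if impute_means is None and all_missing:
        raise ConfigurationError(
            f"external feature column(s) {all_missing} absent from the corpus"
        )
    means = impute_means if impute_means is not None else table.mean()
    return table.fillna(means)


def windowize(
    table: pd.DataFrame, W: int = 9, col_means: pd.Series | None = None
) -> pd.DataFrame:
    """Concatenate each residue's window of feature vectors into one row.

    For W >= 3 the row holds the feature vectors at offsets
    -(W-1)/2 ... +(W-1)/2 within the same record; W = 0 keeps the central
    residue only.  Off-chain positions are filled with ``col_means``
    (training-set column means; defaults to the means of ``table``).
    Even W >= 2 is rejected.
    """
    if W < 0 or (W >= 2 and W % 2 == 0):
        raise ValueError(f"window W must be 0 or odd, got {W}")
    if W in (0, 1):
        return table.copy()
    half = (W - 1) // 2
    means = (col_means if col_means is not None else table.mean()).reindex(
        table.columns
    )
    pieces = []
    values = table.to_numpy()
    # per-record shifted views, padded with column means
    rec_codes = table.index.get_level_values(0)
    boundaries = np.flatnonzero(
        np.r_[True, rec_codes[1:] != rec_codes[:-1], True]
    )
    for off in range(-half, half + 1):
        shifted = np.tile(means.to_numpy(), (len(table), 1))
        for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
            block = values[b0:b1]
            n = b1 - b0
            src_lo, src_hi = max(0, off), min(n, n + off)
            dst_lo, dst_hi = max(0, -off), min(n, n - off)
            shifted[b0 + dst_lo : b0 + dst_hi] = block[src_lo:src_hi]
        cols = [f"{c}@{off:+d}" for c in table.columns]
        pieces.append(pd.DataFrame(shifted, index=table.index, columns=cols))
    return pd.concat(pieces, axis=1)


@dataclass
class FeatureMatrix:
    """Windowed numeric matrix with labels and residue provenance."""

    X: np.ndarray
    y: np.ndarray  # 1 = epitope, 0 = non-epitope, -1 = unlabeled
    index: pd.MultiIndex  # (record_id, position)
    columns: list[str]

    @property
    def labeled(self) -> np.ndarray:
        return self.y >= 0

    @property
    def groups(self) -> np.ndarray:
        return self.index.get_level_values(0).to_numpy()


@dataclass
class FeaturePipeline:
    """Fit-once/transform-many feature builder for one training corpus.

    ``fit`` trains the composition ratios, both potential models and the
    imputation/padding means on the training records; ``transform`` then
    produces the windowed matrix for any corpus with the same column layout.
    """

    registry: FeatureRegistry
    W: int = 9
    interval: int = 7
    sigma: float = 10.0
    ratios: CompositionRatios | None = None
    pot_epitope: FrequencyModel | None = None
    pot_exposure: FrequencyModel | None = None
    col_means: pd.Series | None = field(default=None, repr=False)

    def _needs(self, source_or_name) -> bool:
        return any(
            f.name == source_or_name or f.source == source_or_name
            for f in self.registry
        )

    def fit(self, corpus: Corpus) -> "FeaturePipeline":
        if self._needs("F1") or self._needs("F2"):
            self.ratios = fit_composition_ratios(corpus)
        if self._needs("F9"):
            self.pot_epitope = train_frequency_model(
                corpus, "epitope", self.interval, self.sigma
            )
        if self._needs("F11"):
            self.pot_exposure = train_frequency_model(
                corpus, "exposure", self.interval, self.sigma
            )
        base = assemble_residue_features(
            corpus,
            self.registry,
            ratios=self.ratios,
            pot_epitope=self.pot_epitope,
            pot_exposure=self.pot_exposure,
        )
        self.col_means = base.mean()
        return self

    def transform(self, corpus: Corpus) -> FeatureMatrix:
        if self.col_means is None:
            raise RuntimeError("pipeline is not fitted")
        base = assemble_residue_features(
            corpus,
            self.registry,
            ratios=self.ratios,
            pot_epitope=self.pot_epitope,
            pot_exposure=self.pot_exposure,
            impute_means=self.col_means,
        )
        wide = windowize(base, self.W, self.col_means)
        labels = np.concatenate(
            [
                np.array([{"E": 1, "N": 0}.get(c, -1) for c in rec.labels])
                for rec in corpus
            ]
        )
        return FeatureMatrix(
            X=wide.to_numpy(dtype=float),
            y=labels,
            index=wide.index,
            columns=list(wide.columns),
        )

    def fit_transform(self, corpus: Corpus) -> FeatureMatrix:
        return self.fit(corpus).transform(corpus)
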