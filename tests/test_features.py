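"""Composition ratios, hydrophilicity, feature assembly and windowing."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

import episeq as eq
from episeq.features import (
    HOPP_WOODS,
    ConfigurationError,
    FeatureDef,
    FeaturePipeline,
    FeatureRegistry,
    fit_composition_ratios,
    windowize,
)
from episeq.seqdata import AMINO_ACIDS, AntigenRecord, Corpus


def _hand_ratios(corpus):
    """Independent recount of the smoothed composition ratios."""
    epi, non, surf = Counter(), Counter(), Counter()
    for rec in corpus:
        for i, aa in enumerate(rec.sequence):
            if aa not in AMINO_ACIDS:
                continue
            if rec.labels[i] == "E":
                epi[aa] += 1
            elif rec.labels[i] == "N":
                non[aa] += 1
                if rec.exposure[i] == "E":
                    surf[aa] += 1

    def freqs(counter):
        tot = sum(counter[a] + 1 for a in AMINO_ACIDS)
        return {a: (counter[a] + 1) / tot for a in AMINO_ACIDS}

    fe, fn, fs = freqs(epi), freqs(non), freqs(surf)
    return (
        {a: fe[a] / fs[a] for a in AMINO_ACIDS},
        {a: fe[a] / fn[a] for a in AMINO_ACIDS},
    )


def test_composition_ratios_match_hand_count(toy):
    ratios = fit_composition_ratios(toy)
    surf, antigen = _hand_ratios(toy)
    for i, a in enumerate(AMINO_ACIDS):
        assert ratios.ratio_surface[i] == pytest.approx(surf[a], abs=1e-12)
        assert ratios.ratio_antigen[i] == pytest.approx(antigen[a], abs=1e-12)


def test_identical_composition_gives_unit_ratios():
    """Epitope and background drawn from the same composition: ratios ~1."""
    seq = "ACDEFGHIKLMNPQRSTVWY" * 10
    labels = ("E" * 20 + "N" * 20) * 5  # every type equally often in E and N
    rec = AntigenRecord(
        id="a", sequence=seq, labels=labels, exposure="E" * len(seq)
    )
    ratios = fit_composition_ratios(Corpus([rec]))
    np.testing.assert_allclose(ratios.ratio_antigen, 1.0, rtol=0.01)
    np.testing.assert_allclose(ratios.ratio_surface, 1.0, rtol=0.01)


def test_type_absent_from_epitopes_has_small_positive_ratio():
    rec = AntigenRecord(
        id="a",
        sequence="W" * 5 + "A" * 45,
        labels="N" * 5 + "E" * 5 + "N" * 40,
        exposure="E" * 50,
    )
    ratios = fit_composition_ratios(Corpus([rec]))
    w = AMINO_ACIDS.index("W")
    assert 0 < ratios.ratio_antigen[w] < 1


def test_hydrophilicity_scale_properties():
    all_asp = eq.hydrophilicity("DDDD")
    assert np.all(all_asp == max(HOPP_WOODS.values()))
    d, a, w = eq.hydrophilicity("DAW")
    assert d > a > w
    x = eq.hydrophilicity("X")[0]
    assert x == pytest.approx(np.mean(list(HOPP_WOODS.values())))


def test_assemble_reduced_registry(toy):
    pipe = FeaturePipeline(registry=FeatureRegistry.reduced(), W=0).fit(toy)
    fm = pipe.transform(toy)
    assert fm.columns == ["F1", "F2", "F3", "F9", "F11"]
    assert fm.X.shape == (toy.n_residues, 5)
    assert np.isfinite(fm.X).all()


def test_assemble_column_count_and_multicolumn_externals(planted_small):
    reg = FeatureRegistry.with_external(
        {"acc_pred": ("acc_pred",), "solub": ("solub",), "flex": ("flex",)}
    )
    pipe = FeaturePipeline(registry=reg, W=0).fit(planted_small)
    fm = pipe.transform(planted_small)
    assert fm.X.shape[1] == sum(f.arity for f in reg)


def test_missing_external_cells_imputed_with_training_mean(planted_small):
    reg = FeatureRegistry.with_external({"acc_pred": ("acc_pred",)})
    # hide some values in one record
    corpus = planted_small
    rec = corpus.records[0]
    original = rec.extra_features["acc_pred"].copy()
    rec.extra_features["acc_pred"][3:8] = np.nan
    try:
        pipe = FeaturePipeline(registry=reg, W=0).fit(corpus)
        fm = pipe.transform(corpus)
        col = fm.X[:, fm.columns.index("acc_pred")]
        # independent mean over all non-missing cells
        vals = np.concatenate(
            [r.extra_features["acc_pred"] for r in corpus]
        )
        expect = np.nanmean(vals)
        assert col[3] == pytest.approx(expect, abs=1e-12)
    finally:
        rec.extra_features["acc_pred"] = original


def test_entirely_missing_external_raises(toy):
    reg = FeatureRegistry.with_external({"ghost": ("ghost",)})
    with pytest.raises(ConfigurationError, match="ghost"):
        FeaturePipeline(registry=reg, W=0).fit(toy)


def test_windowize_widths(rng):
    idx = pd.MultiIndex.from_arrays(
        [["r"] * 30, range(30)], names=["record_id", "position"]
    )
    table = pd.DataFrame(
        rng.normal(size=(30, 13)), index=idx,
        columns=[f"c{i}" for i in range(13)],
    )
    assert windowize(table, 0).shape[1] == 13
    assert windowize(table, 9).shape[1] == 117
    with pytest.raises(ValueError):
        windowize(table, 4)


def test_windowize_pads_termini_with_column_means(rng):
    idx = pd.MultiIndex.from_arrays(
        [["r"] * 6, range(6)], names=["record_id", "position"]
    )
    table = pd.DataFrame(
        rng.normal(size=(6, 2)), index=idx, columns=["a", "b"]
    )
    means = pd.Series({"a": 10.0, "b": -10.0})
    wide = windowize(table, 3, col_means=means)
    assert wide.iloc[0]["a@-1"] == 10.0
    assert wide.iloc[0]["b@-1"] == -10.0
    assert wide.iloc[0]["a@+0"] == table.iloc[0]["a"]
    assert wide.iloc[1]["a@-1"] == table.iloc[0]["a"]
    assert wide.iloc[-1]["b@+1"] == -10.0


def test_windowize_translation_consistency(rng):
    """Interior rows equal the rows computed from an embedding super-sequence
    with enough flanking context."""
    W, half, flank = 5, 2, 4
    sub_vals = rng.normal(size=(12, 3))
    super_vals = np.vstack(
        [rng.normal(size=(flank, 3)), sub_vals, rng.normal(size=(flank, 3))]
    )

    def as_table(vals):
        idx = pd.MultiIndex.from_arrays(
            [["r"] * len(vals), range(len(vals))],
            names=["record_id", "position"],
        )
        return pd.DataFrame(vals, index=idx, columns=list("abc"))

    means = pd.Series({"a": 0.0, "b": 0.0, "c": 0.0})
    sub = windowize(as_table(sub_vals), W, means).to_numpy()
    sup = windowize(as_table(super_vals), W, means).to_numpy()
    np.testing.assert_allclose(
        sub[half:-half], sup[flank + half : flank + 12 - half], atol=0
    )


def test_dropping_feature_changes_only_its_columns(toy):
    full = FeaturePipeline(registry=FeatureRegistry.reduced(), W=0).fit(toy)
    fm_full = full.transform(toy)
    reduced_reg = FeatureRegistry.reduced().subset(["F1", "F2", "F9", "F11"])
    part = FeaturePipeline(registry=reduced_reg, W=0).fit(toy)
    fm_part = part.transform(toy)
    for name in ["F1", "F2", "F9", "F11"]:
        np.testing.assert_allclose(
            fm_full.X[:, fm_full.columns.index(name)],
            fm_part.X[:, fm_part.columns.index(name)],
            atol=0,
        )


def test_assembly_is_deterministic(planted_small):
    reg = FeatureRegistry.reduced()
    a = FeaturePipeline(registry=reg, W=3).fit(planted_small).transform(planted_small)
    b = FeaturePipeline(registry=reg, W=3).fit(planted_small).transform(planted_small)
    np.testing.assert_array_equal(a.X, b.X)
    np.testing.assert_array_equal(a.y, b.y)


def test_feature_def_validation():
    with pytest.raises(ConfigurationError):
        FeatureDef("F1", "telepathy")
    with pytest.raises(ConfigurationError):
        FeatureRegistry((FeatureDef("F1", "computed"), FeatureDef("F1", "computed")))
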