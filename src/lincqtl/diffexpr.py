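"""Differential expression between two breeds without biological replicates.

Expression is quantified as FPKM (fragments per kilobase of exon per
million mapped fragments); gene FPKM is the sum of its transcripts' FPKMs.
Fold change is numerator-breed over denominator-breed FPKM after adding a
small pseudocount so that zero-expression features yield finite ratios.

With a single library per condition no dispersion can be estimated, so the
p-value engine is the exact conditional binomial test: conditional on the
total fragment count n = x1 + x2 of a feature, x1 ~ Binomial(n, p0) under
the null, where p0 is the first library's share of the combined sequencing
depth.  External per-feature p-values may be supplied instead.

Two named threshold presets are provided:

* ``results_text`` — q < 0.05 and fold change >= 2 or <= 0.5 (inclusive
  boundaries); the default.
* ``methods_text`` — q < 0.01 and |log2 fold change| > 1 (strict), so a
  feature with fold change exactly 2 is *ns* under this preset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

from .models import ValidationError

STATUS_UP, STATUS_DOWN, STATUS_NS = "up", "down", "ns"


@dataclass(frozen=True)
class DEParams:
    """Thresholds and pseudocount for differential-expression calls."""

    pseudocount: float = 0.01
    q_threshold: float = 0.05
    fc_up: float = 2.0
    fc_down: float = 0.5
    fc_inclusive: bool = True
    preset: str = "results_text"

    def __post_init__(self) -> None:
        if not 0 < self.q_threshold < 1:
            raise ValidationError("q_threshold must be in (0,1)")
        if not math.isclose(self.fc_up * self.fc_down, 1.0, rel_tol=1e-9):
            raise ValidationError("fc_up must equal 1/fc_down")

    @classmethod
    def results_text(cls) -> "DEParams":
        """FDR < 0.05 and fold change >= 2 or <= 0.5."""
        return cls()

    @classmethod
    def methods_text(cls) -> "DEParams":
        """Q < 0.01 and |log2 fold change| > 1 (strict boundaries)."""
        return cls(q_threshold=0.01, fc_inclusive=False, preset="methods_text")

    @classmethod
    def from_preset(cls, name: str) -> "DEParams":
        try:
            return {"results_text": cls.results_text, "methods_text": cls.methods_text}[name]()
        except KeyError:
            raise ValidationError(f"unknown DE preset {name!r}") from None


def compute_fpkm(fragments, spliced_length, library_size):
    """FPKM = fragments * 1e9 / (spliced_length * library_size).

    Accepts scalars or aligned numpy/pandas arrays.
    """
    spliced_length = np.asarray(spliced_length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if (spliced_length <= 0).any() if spliced_length.ndim else spliced_length <= 0:
        raise ValidationError("spliced_length must be > 0")
    if (library_size <= 0).any() if library_size.ndim else library_size <= 0:
        raise ValidationError("library_size must be > 0")
    out = np.asarray(fragments, dtype=float) * 1e9 / (spliced_length * library_size)
    return float(out) if out.ndim == 0 else out


def gene_fpkm(transcript_fpkm: pd.Series, tx2gene: Mapping[str, str]) -> pd.Series:
    """Gene-level FPKM: the sum of member-transcript FPKMs."""
    groups = pd.Series({t: tx2gene[t] for t in transcript_fpkm.index})
    return transcript_fpkm.groupby(groups).sum()


def fold_change(fpkm_num: float, fpkm_den: float, pseudocount: float = 0.01):
    """Fold change (numerator+c)/(denominator+c) and its log2."""
    fc = (fpkm_num + pseudocount) / (fpkm_den + pseudocount)
    return fc, math.log2(fc)


def de_pvalue(frag_1: int, frag_2: int, lib_1: float, lib_2: float) -> float:
    """Two-sided exact conditional binomial p-value for one feature.

    Tests frag_1 ~ Binomial(frag_1 + frag_2, lib_1/(lib_1+lib_2)); a
    feature with zero fragments in both libraries gives p = 1.
    """
    n = int(frag_1) + int(frag_2)
    if n == 0:
        return 1.0
    p0 = lib_1 / (lib_1 + lib_2)
    return float(binomtest(int(frag_1), n, p0, alternative="two-sided").pvalue)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def call_status(fc: float, q: float, params: DEParams) -> str:
    if q < params.q_threshold:
        if (fc >= params.fc_up) if params.fc_inclusive else (fc > params.fc_up):
            return STATUS_UP
        if (fc <= params.fc_down) if params.fc_inclusive else (fc < params.fc_down):
            return STATUS_DOWN
    return STATUS_NS


def call_de(results: pd.DataFrame, params: DEParams = DEParams()) -> pd.DataFrame:
    """Add a status column (up/down/ns) from fold_change and q_value."""
    out = results.copy()
    out["status"] = [
        call_status(fc, q, params)
        for fc, q in zip(out["fold_change"], out["q_value"])
    ]
    return out


def differential_expression(
    expression,
    groups: Mapping[str, str],
    numerator: str = "Luchuan",
    denominator: str = "Duroc",
    params: DEParams = DEParams(),
    tx2gene: Optional[Mapping[str, str]] = None,
    external_pvalues: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Per-feature DE table between two groups of samples.

    Fragments and library sizes are pooled within each group; FPKM per
    group is the mean over the group's samples.  With ``tx2gene`` the
    table is aggregated to gene level first (FPKMs summed, fragments
    summed).  ``external_pvalues`` (indexed by feature) bypasses the
    built-in binomial test.

    Returns a DataFrame indexed by feature with columns ``fpkm_<num>``,
    ``fpkm_<den>``, ``fold_change``, ``log2fc``, ``p_value``, ``q_value``,
    ``status``.
    """
    samples_1 = [s for s, g in groups.items() if g == numerator]
    samples_2 = [s for s, g in groups.items() if g == denominator]
    if not samples_1 or not samples_2:
        raise ValidationError(
            f"groups must contain samples for both {numerator!r} and {denominator!r}"
        )
    fpkm_1 = expression.fpkm[samples_1].mean(axis=1)
    fpkm_2 = expression.fpkm[samples_2].mean(axis=1)
    frag_1 = expression.fragments[samples_1].sum(axis=1)
    frag_2 = expression.fragments[samples_2].sum(axis=1)
    lib_1 = float(expression.library_sizes[samples_1].sum())
    lib_2 = float(expression.library_sizes[samples_2].sum())

    if tx2gene is not None:
        key = pd.Series({f: tx2gene[f] for f in fpkm_1.index})
        fpkm_1 = fpkm_1.groupby(key).sum()
        fpkm_2 = fpkm_2.groupby(key).sum()
        frag_1 = frag_1.groupby(key).sum()
        frag_2 = frag_2.groupby(key).sum()

    fcs, lfcs = zip(
        *(fold_change(a, b, params.pseudocount) for a, b in zip(fpkm_1, fpkm_2))
    ) if len(fpkm_1) else ((), ())
    if external_pvalues is not None:
        pvals = external_pvalues.reindex(fpkm_1.index)
        if pvals.isna().any():
            raise ValidationError("external p-values missing for some features")
        pvals = pvals.to_numpy(dtype=float)
    else:
        pvals = np.array(
            [de_pvalue(a, b, lib_1, lib_2) for a, b in zip(frag_1, frag_2)]
        )
    result = pd.DataFrame(
        {
            f"fpkm_{numerator}": fpkm_1,
            f"fpkm_{denominator}": fpkm_2,
            "fold_change": fcs,
            "log2fc": lfcs,
            "p_value": pvals,
            "q_value": bh_adjust(pvals),
        },
        index=fpkm_1.index,
    )
    result.index.name = "feature_id"
    return call_de(result, params)
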