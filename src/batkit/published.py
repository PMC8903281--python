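"""Published Bayesian model-comparison tables from the BAT training study.

The large beat-alignment study this package models (N = 458: young adults,
older adults, and people with Parkinson's disease; music and dance training
binned 0-2 vs 3+ years) reported eight Bayesian ANOVA model-comparison
tables: for each of the four outcome measures (perception percent correct,
asynchrony, coefficient of deviation, coefficient of variation), one
comparison over music training x group and one over dance training x group
(the dance analyses exclude the Parkinson's group, which had a single
dance-trained member).

Each table lists five candidate models with uniform prior probability 0.20.
The printed BF_10 columns are reproduced here as inputs: feeding them through
:func:`batkit.bayes.posterior_model_probs` recovers the published
``P(M|data)`` and ``BF_M`` columns.  ``posterior_prob`` and ``bf_m`` below
are the study's printed values, kept for cross-checking; a few printed BF_M
entries are internally inconsistent with their own BF_10 column (rounding in
the source), which the recomputation exposes.
"""

from __future__ import annotations

from .bayes import BayesModelRow

__all__ = ["PUBLISHED_COMPARISONS", "published_rows"]

# key -> list of (model terms, BF_10, printed P(M|data), printed BF_M)
PUBLISHED_COMPARISONS: dict[str, list[tuple[tuple[str, ...], float, float, float]]] = {
    "perception_music": [
        ((), 1.00, 0.00, 0.00),
        (("music",), 685845.0, 0.89, 33.23),
        (("music", "group", "music:group"), 46220.0, 0.06, 0.26),
        (("music", "group"), 36339.0, 0.05, 0.20),
        (("group",), 0.12, 0.00, 0.00),
    ],
    "perception_dance": [
        ((), 1.00, 0.57, 0.57),
        (("dance",), 0.33, 0.19, 0.19),
        (("group",), 0.29, 0.17, 0.17),
        (("dance", "group"), 0.10, 0.06, 0.06),
        (("dance", "group", "dance:group"), 0.02, 0.01, 0.01),
    ],
    "asynchrony_music": [
        ((), 1.00, 0.40, 2.72),
        (("music",), 0.61, 0.25, 1.30),
        (("music", "group", "music:group"), 0.38, 0.15, 0.73),
        (("music", "group"), 0.30, 0.12, 0.55),
        (("group",), 0.19, 0.08, 0.33),
    ],
    "asynchrony_dance": [
        ((), 1.00, 0.76, 12.86),
        (("dance",), 0.17, 0.13, 0.59),
        (("group",), 0.12, 0.09, 0.40),
        (("dance", "group"), 0.02, 0.02, 0.06),
        (("dance", "group", "dance:group"), 0.01, 0.00, 0.02),
    ],
    "tempo_music": [
        ((), 1.00, 0.60, 5.97),
        (("music",), 0.50, 0.30, 1.72),
        (("music", "group", "music:group"), 0.12, 0.07, 0.31),
        (("music", "group"), 0.04, 0.03, 0.11),
        (("group",), 0.00, 0.00, 0.01),
    ],
    "tempo_dance": [
        ((), 1.00, 0.69, 8.73),
        (("dance",), 0.22, 0.15, 0.71),
        (("group",), 0.18, 0.12, 0.56),
        (("dance", "group"), 0.04, 0.03, 0.11),
        (("dance", "group", "dance:group"), 0.02, 0.01, 0.05),
    ],
    "variability_music": [
        ((), 1.00, 0.00, 0.00),
        (("music", "group"), 5.30e9, 0.79, 14.90),
        (("music", "group", "music:group"), 1.19e9, 0.17, 0.84),
        (("music",), 2.65e8, 0.04, 0.16),
        (("group",), 301.27, 0.00, 0.00),
    ],
    "variability_dance": [
        ((), 1.00, 0.05, 0.20),
        (("group",), 16.78, 0.79, 15.02),
        (("dance",), 2.62, 0.12, 0.56),
        (("dance", "group"), 0.68, 0.03, 0.13),
        (("dance", "group", "dance:group"), 0.16, 0.01, 0.03),
    ],
}


def published_rows(key: str) -> list[BayesModelRow]:
    """The published BF_10 column of one comparison as fresh input rows.

    Prior probability is the study's uniform 0.20; posterior and BF_M are
    left unset so they can be recomputed and checked against the printed
    columns.
    """
    table = PUBLISHED_COMPARISONS[key]
    return [
        BayesModelRow(model_terms=terms, prior_prob=1.0 / len(table), bf10=bf)
        for terms, bf, _post, _bfm in table
    ]
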