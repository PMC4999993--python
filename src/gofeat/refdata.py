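"""Published reference figures used for internal-consistency checks.

``BENCHMARK_SUMMARY`` holds the published human CAFA2-style evaluation
summary for the three predictors (per-term SVM library, identity-transfer
BLAST baseline, annotation-frequency Naive baseline) on each GO domain: the
F-maximising decision threshold, the summed confusion counts, the number of
covered proteins, and the averaged precision, recall and F1.  The averaged
precision/recall pairs and the F1 column are redundant given the F-measure
definition, which makes the table a worked example for
:func:`gofeat.evaluation.pr_curve`-style arithmetic.

``CLASSIFIER_VOCABULARY`` and ``NAIVE_TABLE_SIZES`` record the published
per-domain term counts of the evaluation-time classifier library and of the
Naive score table, with their published totals.
"""

# columns: domain, method, threshold, TP, FP, FN, NP, precision, recall, F1
BENCHMARK_SUMMARY = [
    ("MF", "SVM",   0.581, 1443, 3457, 1818, 427, 0.390, 0.461, 0.422),
    ("MF", "BLAST", 0.210, 952, 5740, 2309, 216, 0.266, 0.282, 0.274),
    ("MF", "Naive", 0.152, 1081, 1643, 2180, 454, 0.397, 0.391, 0.394),
    ("BP", "SVM",   0.576, 5792, 13013, 14469, 655, 0.353, 0.331, 0.342),
    ("BP", "BLAST", 0.203, 5272, 83543, 14989, 345, 0.173, 0.271, 0.211),
    ("BP", "Naive", 0.273, 4136, 8423, 16125, 661, 0.329, 0.241, 0.278),
    ("CC", "SVM",   0.730, 3800, 7424, 4576, 985, 0.369, 0.500, 0.425),
    ("CC", "BLAST", 0.204, 2030, 15655, 6346, 422, 0.215, 0.251, 0.232),
    ("CC", "Naive", 0.579, 2869, 3077, 5507, 991, 0.483, 0.340, 0.399),
]

#: per-domain classifier counts of the evaluation-time library and the total
CLASSIFIER_VOCABULARY = {"BP": 400, "MF": 108, "CC": 89}
CLASSIFIER_VOCABULARY_TOTAL = 597

#: per-domain Naive (term, score) table sizes and the total
NAIVE_TABLE_SIZES = {"CC": 469, "MF": 1268, "BP": 4767}
NAIVE_TABLE_TOTAL = 6504
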