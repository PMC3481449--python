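"""Standardize and quantize a small expression matrix.

Builds a 3-gene x 8-time-point real-valued matrix, applies the normal
transformation (mean 0, sd 1 per gene) and the ternary threshold
mapping (h=0.5, l=-0.5), and prints the result: +1 up-regulated,
-1 down-regulated, 0 basal, 3 not observed.
"""

import numpy as np

from entgain import ExpressionMatrix, QuantizationThresholds, quantize

raw = ExpressionMatrix(
    ["pfA", "pfB", "pfC"],
    np.array(
        [
            [0.1, 0.9, 2.0, 1.1, 0.2, -0.8, -2.1, -1.0],
            [5.0, 5.5, 6.5, 7.0, 6.4, 5.6, np.nan, 5.1],
            [-1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0],
        ]
    ),
)

q = quantize(raw, QuantizationThresholds(h=0.5, l=-0.5))
print("gene  quantized series (3 = not observed)")
for g in q.gene_ids:
    print(f"{g:5s}", " ".join(f"{v:2d}" for v in q.series(g)))
print()
print("Each row is one gene's regulation level over time after per-gene")
print("standardization; the NaN in pfB survived as the missing code 3.")
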