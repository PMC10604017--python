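"""Bundled published similarity grid for validation and demos.

The grid below is the published table of cosine similarity scores between
NMF-resolved spectra and four reference materials (glass substrate,
acrylamide resin, the immobilized pantothenate kinase PanK, and the
Bis-Tris wash buffer) for a Raman hyperspectral map of enzyme immobilized
on acrylamide resin, acquired at 785 nm excitation.  Models were built with
1..10 components; each row is one component of one model.  It serves as a
worked example for the selection rule: with the default thresholds the
8-component model is selected, assigning resin (0.98), glass (0.97),
Bis-Tris (0.84) and PanK (0.77).
"""

from __future__ import annotations

import io

import pandas as pd

from .similarity import SimilarityGrid

_AC_RESIN_785_CSV = """\
model_k,component,Glass,Acrylamide Resin,PanK,Bis-Tris
1,1,0.48,0.99,0.90,0.62
2,1,0.44,0.99,0.89,0.62
2,2,0.96,0.66,0.66,0.40
3,1,0.44,0.98,0.89,0.60
3,2,0.97,0.60,0.62,0.31
3,3,0.27,0.80,0.65,0.82
4,1,0.44,0.98,0.90,0.60
4,2,0.97,0.62,0.63,0.34
4,3,0.26,0.81,0.65,0.81
4,4,0.20,0.44,0.44,0.40
5,1,0.44,0.98,0.90,0.60
5,2,0.96,0.62,0.64,0.34
5,3,0.27,0.81,0.65,0.82
5,4,0.20,0.40,0.38,0.43
5,5,0.44,0.77,0.67,0.50
6,1,0.44,0.98,0.89,0.59
6,2,0.96,0.61,0.62,0.33
6,3,0.24,0.76,0.61,0.83
6,4,0.21,0.34,0.31,0.37
6,5,0.39,0.75,0.66,0.54
6,6,0.20,0.60,0.73,0.43
7,1,0.44,0.98,0.89,0.59
7,2,0.96,0.62,0.61,0.33
7,3,0.24,0.74,0.61,0.82
7,4,0.18,0.31,0.28,0.33
7,5,0.36,0.66,0.62,0.43
7,6,0.17,0.68,0.59,0.64
7,7,0.23,0.45,0.71,0.26
8,1,0.44,0.98,0.88,0.59
8,2,0.97,0.61,0.60,0.33
8,3,0.28,0.72,0.61,0.84
8,4,0.17,0.30,0.28,0.33
8,5,0.37,0.62,0.58,0.45
8,6,0.16,0.68,0.59,0.64
8,7,0.31,0.55,0.77,0.30
8,8,0.23,0.57,0.69,0.35
9,1,0.44,0.98,0.88,0.59
9,2,0.97,0.60,0.60,0.32
9,3,0.25,0.73,0.61,0.83
9,4,0.17,0.30,0.27,0.33
9,5,0.38,0.63,0.58,0.47
9,6,0.22,0.68,0.72,0.60
9,7,0.36,0.58,0.80,0.41
9,8,0.26,0.62,0.72,0.39
9,9,0.20,0.60,0.54,0.48
10,1,0.44,0.98,0.88,0.59
10,2,0.97,0.60,0.59,0.32
10,3,0.24,0.74,0.60,0.83
10,4,0.18,0.32,0.28,0.34
10,5,0.39,0.63,0.58,0.47
10,6,0.25,0.68,0.72,0.60
10,7,0.31,0.57,0.78,0.40
10,8,0.22,0.65,0.69,0.42
10,9,0.21,0.58,0.55,0.46
10,10,0.57,0.63,0.71,0.44
"""


def published_similarity_grid() -> SimilarityGrid:
    """The bundled PanK-on-acrylamide-resin (785 nm) similarity grid."""
    return SimilarityGrid(pd.read_csv(io.StringIO(_AC_RESIN_785_CSV)))
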