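"""Packaged fit-table fixture from the full-scale plant study.

The classification fit values (SENS/SPEC on testing data, per family,
per predictor combination) from the plant campaign are shipped verbatim
as a fit table so the ranking and selection-matrix machinery can be
exercised without the undeposited raw plant data.  Letters: A=BOD,
B=TN, C=TP, D=T, E=MLSS, F=DO, G=m_PIX; slashes are element-wise ratio
features (A/B = BOD/TN).  SP=SPEC, SE=SENS; BT/RF annotate the selected
tree count, MLP the hidden size and hidden/output activations, SVM the
(C; gamma) pair.
"""
from __future__ import annotations

import io

import pandas as pd

__all__ = ["fixture_table2"]

_TABLE2_CSV = '''combo,BT_SP,BT_SE,BT_hp,LR_SP,LR_SE,MLP_SP,MLP_SE,MLP_hp,SVM_SP,SVM_SE,SVM_hp,RF_SP,RF_SE,RF_hp
A,0.65,0.81,19,0.27,0.88,0.42,0.87,"5:exp,lin",0.38,0.92,"900;0.35",0.46,0.88,170
B,0.88,0.81,88,0.35,0.94,0.31,0.96,"4:sin,lin",0.31,0.98,"100;0.40",0.35,0.88,60
C,0.62,0.83,19,0.27,0.92,0.46,0.88,"3:lin,lin",0.50,0.85,"1000;0.25",0.46,0.88,20
"A,B",0.85,0.83,19,0.38,0.90,0.48,0.92,"8:exp,tanh",0.42,0.98,"800;0.35",0.00,1.00,25
A/B,0.77,0.73,11,0.27,0.85,0.35,0.94,"3:tanh,lin",0.54,0.85,"800;0.25",0.58,0.81,40
A/C,0.73,0.75,38,0.35,0.85,0.35,0.92,"3:sin,lin",0.50,0.90,"800;0.35",0.69,0.79,40
"A,C",0.65,0.75,11,0.27,0.85,0.31,0.94,"3:tanh,lin",0.54,0.87,"800;0.80",0.58,0.79,40
D,0.81,0.88,183,0.65,0.87,0.73,0.85,"3:exp,sin",0.62,0.88,"900;0.33",0.88,0.77,30
"D,A/B",0.88,0.77,10,0.68,0.87,0.65,0.87,"4:lin,exp",0.73,0.85,"800;0.35",0.88,0.81,40
"D,A/C",0.88,0.88,155,0.68,0.88,0.69,0.85,"3:lin,lin",0.73,0.87,"800;0.33",0.88,0.80,30
"D,B",0.88,0.77,10,0.62,0.88,0.65,0.90,"7:tanh,lin",0.73,0.87,"900;0.33",0.88,0.82,10
"D,B,C",0.88,0.80,24,0.62,0.88,0.68,0.90,"6:tanh,lin",0.76,0.88,"800;0.25",0.88,0.86,30
"D,A,B,C",0.92,0.83,14,0.65,0.92,0.69,0.94,"9:lin,sin",0.77,0.90,"1000;0.25",0.85,0.87,30
E,0.88,0.75,119,0.62,0.83,0.88,0.92,"5:log,exp",0.85,0.88,"900;0.40",0.50,0.98,119
"E,D",0.95,0.96,98,0.88,0.96,0.92,1.00,"5:exp,lin",1.00,0.98,"900;0.25",0.88,0.92,30
"E,F",0.96,0.87,98,0.65,0.90,0.88,0.96,"5:lin,lin",0.88,0.96,"900;0.20",0.46,1.00,200
F,0.92,0.81,195,0.00,1.00,0.46,0.90,"4:tanh,tanh",0.58,0.85,"900;0.50",0.92,0.71,30
"D,F",0.88,0.77,15,0.62,0.88,0.73,0.85,"7:log,lin",0.65,0.88,"700;0.33",0.88,0.77,30
"D,F,B",0.92,0.90,15,0.65,0.90,0.69,0.90,"7:exp,lin",0.69,0.90,"700;0.25",0.85,0.85,30
"D,F,A/B",0.90,0.84,5,0.70,0.88,0.85,0.79,"6:tanh,lin",0.81,0.87,"900;0.33",0.88,0.77,30
"D,F,B,C",0.88,0.81,10,0.65,0.90,0.69,0.92,"8:tanh,tanh",0.81,0.88,"800;0.25",0.88,0.85,30
"F,B",0.85,0.88,114,0.35,0.92,0.50,0.87,"3:tanh,tanh",0.46,0.96,"700;0.20",0.88,0.77,140
"F,B,C",0.92,0.92,186,0.31,0.94,0.55,0.96,"5:sin,lin",0.54,0.85,"500;0.35",0.54,0.85,20
"F,C",0.85,0.73,15,0.23,0.90,0.50,0.88,"3:lin,lin",0.54,0.87,"600;0.40",0.50,0.75,30
"D,F,E",1.00,0.93,162,0.88,0.96,0.96,0.98,"7:exp,lin",0.96,0.98,"600;0.25",0.08,1.00,30
"A/C,F,E",1.00,0.88,119,0.69,0.90,0.88,0.94,"7:lin,lin",0.88,0.94,"600;0.35",0.85,1.00,30
"A/C,F,E,D",1.00,0.96,195,0.92,0.96,0.91,0.95,"7:lin,sin",0.93,1.00,"600;0.20",0.46,1.00,60
"A/C,A/B,F,E,D",1.00,0.97,100,0.94,0.96,0.92,1.00,"3:tanh,exp",0.94,0.98,"200;0.33",0.88,1.00,100
"B,C,E,F,D",1.00,0.96,119,0.96,0.94,0.95,1.00,"8:tanh,lin",0.88,0.98,"100;0.17",0.81,1.00,70
"B,C,E,F,D,G",1.00,0.98,195,0.96,0.98,0.99,1.00,"4:lin,lin",0.92,0.98,"100;0.25",0.88,0.96,70
"B,C,E,F",0.96,0.88,195,0.85,0.94,0.93,0.99,"4:lin,lin",0.69,0.96,"200;0.35",0.66,0.91,70
"B,E,F,D,G",1.00,0.96,195,0.85,0.94,0.95,1.00,"6:lin,tanh",0.92,0.98,"50;0.25",0.85,0.92,30
"B,E,F,D",1.00,0.94,195,0.96,0.96,0.97,1.00,"5:tanh,log",0.92,0.95,"70;0.20",0.73,1.00,30
"A/C,A/B,F,E,D,G",1.00,0.98,195,0.97,0.96,1.00,0.98,"9:exp,lin",0.98,0.99,"100;0.14",0.93,1.00,30
"A/C,A/B,F,E,G",1.00,0.90,119,0.73,0.88,0.81,0.96,"4:lin,lin",0.88,0.94,"900;0.25",0.85,0.96,170
"F,E,G",0.96,0.88,119,0.65,0.90,0.78,0.96,"8:sin,exp",0.81,0.94,"700;0.35",0.77,0.94,30
"F,E,G,D",1.00,0.96,199,0.96,0.96,0.96,0.96,"7:exp,lin",1.00,0.94,"700;0.2",0.81,1.00,40
'''


def fixture_table2() -> pd.DataFrame:
    """The packaged plant fit table as a DataFrame.

    One row per predictor combination; columns <family>_SP, <family>_SE
    in [0, 1] plus hyperparameter annotations, consumable by
    ``rank_models`` and ``build_method_matrix``.
    """
    df = pd.read_csv(io.StringIO(_TABLE2_CSV))
    metric_cols = [c for c in df.columns if c.endswith(("_SP", "_SE"))]
    vals = df[metric_cols].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise AssertionError("fixture fit values outside [0, 1]")
    return df
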