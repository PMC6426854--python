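"""Published core-microbiota table: mean relative abundance (%) of the 13
genus-level taxa with prevalence > 70% in at least three matrices, per
(site, matrix) group across the five production sites P1, P2, P3, RE1, RE2.

A dash in the published table (absence / below the prevalence cut-off) is
encoded as an empty cell and treated as "absent" throughout.
"""

from __future__ import annotations

import io

import pandas as pd

TAXA = [
    "Alistipes",
    "Bacteroides",
    "Bifidobacterium",
    "Corynebacterium 1",
    "Lactobacillus",
    "Ruminococcaceae UCG-005",
    "Ruminococcaceae UCG-010",
    "Streptococcus",
    "U. m. of Actinobacteria class",
    "U. m. of Clostridiaceae 1 family",
    "U. m. of Lachnospiraceae family",
    "U. m. of Peptostreptococcaceae family",
    "U. m. of Ruminococcaceae family",
]

# site<TAB>matrix<TAB>13 abundance columns (percent; empty = absent)
_TABLE1_TSV = """\
P1\tCF\t4.704\t3.640\t0.024\t\t0.003\t\t\t0.001\t0.003\t0.138\t\t0.260\t8.920
P1\tMIL\t0.237\t0.233\t0.524\t\t2.354\t\t\t0.381\t2.601\t0.137\t\t0.697\t0.669
P1\tLIT\t0.207\t0.308\t27.007\t\t47.502\t\t\t4.669\t0.311\t0.156\t\t0.468\t0.168
P1\tPC\t0.009\t0.020\t0.046\t\t87.706\t\t\t10.707\t0.314\t0.012\t\t0.023\t0.013
P2\tCF\t\t\t0.996\t\t\t15.502\t8.951\t0.065\t0.008\t\t10.097\t\t
P2\tMIL\t\t\t0.617\t\t\t1.576\t0.266\t0.099\t4.563\t\t1.918\t\t
P2\tLIT\t\t\t26.584\t\t\t0.990\t0.358\t5.349\t1.286\t\t2.523\t\t
P2\tPC\t\t\t0.038\t\t\t0.007\t0.002\t12.915\t0.266\t\t0.005\t\t
P3\tCF\t\t5.786\t0.120\t0.002\t\t\t\t\t\t\t9.505\t\t
P3\tMIL\t\t0.180\t0.023\t11.698\t\t\t\t\t\t\t0.258\t\t
P3\tLIT\t\t0.750\t3.927\t10.005\t\t\t\t\t\t\t2.902\t\t
P3\tPC\t\t0.111\t0.012\t0.043\t\t\t\t\t\t\t0.016\t\t
RE1\tCF\t\t5.089\t\t\t0.015\t\t\t\t0.001\t0.243\t11.009\t0.221\t
RE1\tMIL\t\t0.459\t\t\t0.663\t\t\t\t7.883\t0.220\t2.242\t1.001\t
RE1\tLIT\t\t4.959\t\t\t21.203\t\t\t\t1.647\t1.054\t5.815\t5.182\t
RE1\tPC\t\t0.063\t\t\t85.654\t\t\t\t0.095\t0.028\t0.053\t0.014\t
RE2\tCF\t\t\t0.013\t\t\t\t\t0.007\t\t\t3.409\t\t
RE2\tMIL\t\t\t0.122\t\t\t\t\t0.043\t\t\t1.053\t\t
RE2\tLIT\t\t\t2.600\t\t\t\t\t1.166\t\t\t1.394\t\t
RE2\tPC\t\t\t0.016\t\t\t\t\t6.869\t\t\t\t0.033\t
"""


def core_table_frame() -> pd.DataFrame:
    """The published core table as a DataFrame.

    Index: MultiIndex (site, matrix); columns: the 13 taxa; values: mean
    relative abundance in percent, NaN where the published table has a dash.
    """
    df = pd.read_csv(
        io.StringIO(_TABLE1_TSV),
        sep="\t",
        header=None,
        names=["site", "matrix"] + TAXA,
    )
    return df.set_index(["site", "matrix"])
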