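"""Packaged transcription of the published head-and-neck cancer cohort.

Fourteen test-set patients (biopsied before radiotherapy, one year of
follow-up) and six negative-validation patients (tissue from already
recurrent tumors).  Columns carry the raw assay readouts (dose-response
AUC, organoid growth rate), clinical covariates (HPV status, TNM, primary
site), outcome (recurrence flag, recurrence-free-survival days) and, as
*annotation only*, the Z-score and OncoSensi index columns as printed in
the source table.  The ``*_printed`` columns are reference values for
regression tests; no computation in this package consumes them.
"""

from __future__ import annotations

import io

import pandas as pd

_TABLE1_CSV = """\
patient_id,set,primary_site,tnm,hpv,recur,rfs_days,rt_auc,growth_rate,z_auc_printed,z_growth_printed,oncosensi_printed
1,test,Base of Tongue,cT3N0M0,negative,no,481,535.7,258.5,0.1556,0.5761,0.712
2,test,Base of Tongue,cT3N2M0,positive,no,512,337.7,200,-1.2579,0.2025,-1.738
3,test,Tonsil,cT3N2M0,positive,no,539,691.1,73.8,1.2651,-1.2493,0.678
4,test,Oropharynx,cT2N2bM0,negative,no,841,543.8,129,0.2135,-0.4361,-0.502
5,test,Oropharynx,cT2N1M0,negative,yes,131,657.3,140,1.0238,-0.3169,0.625
6,test,Tonsil,cT2N1M0,positive,no,463,465.8,82.8,-0.3434,-1.0818,-1.702
7,test,Tonsil,cT2N1M0,positive,no,795,374.9,262,-0.9924,0.5957,-0.777
8,test,Tonsil,cT1N1M0,positive,no,816,565.4,73.6,0.3677,-1.2533,-0.852
9,test,Tonsil,cT2N2M0,positive,no,784,665,83.5,1.0788,-1.0695,0.187
10,test,Tonsil,cT2N1M0,positive,no,631,295.9,417.9,-1.5564,1.2756,0.036
11,test,Tonsil,cT2N2M0,positive,no,446,449.7,424.3,-0.4583,1.2977,1.553
12,test,Tonsil,cT2N1M0,positive,yes,273,384.5,365.4,-0.9238,1.0801,0.659
13,test,Tonsil,cT2N2M0,negative,yes,229,746.5,100,1.6606,-0.8069,1.122
14,test,Oropharynx,cT2N1M0,negative,yes,316,481.3,393,-0.2327,1.1861,1.539
1,validation,Glottis,pT4aN1M0,NA,yes,,719.4,152.6,1.467,-0.188,1.731
2,validation,Glottis,pT2N0M0,NA,yes,,800,139.2,2.043,-0.321,2.335
3,validation,Glottis,pT4aN1M0,NA,yes,,800,143.1,2.043,-0.281,2.386
4,validation,Glottis,pT4N0M0,NA,yes,,800,131.7,2.043,-0.401,2.234
5,validation,Glottis,pT4aN0M0,NA,yes,,634.5,260.4,0.861,0.585,1.895
6,validation,Glottis,pT4aN0M0,NA,yes,,513.1,500,-0.006,1.530,1.926
"""


def table1_fixture() -> pd.DataFrame:
    """The packaged 20-patient cohort (14 test + 6 negative-validation rows)."""
    df = pd.read_csv(
        io.StringIO(_TABLE1_CSV),
        dtype={"patient_id": int},
        na_values=["NA", ""],
    )
    return df


def test_set(df: "pd.DataFrame | None" = None) -> pd.DataFrame:
    df = table1_fixture() if df is None else df
    return df[df["set"] == "test"].reset_index(drop=True)


def validation_set(df: "pd.DataFrame | None" = None) -> pd.DataFrame:
    df = table1_fixture() if df is None else df
    return df[df["set"] == "validation"].reset_index(drop=True)
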