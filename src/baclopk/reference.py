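"""Published reference values for rat baclofen pharmacokinetics under
herbal pretreatment (Oyaksungisan, OY; *Achyranthes bidentata* radix
extract, AB; distilled-water control).

These are the printed summary statistics and population estimates of the
in-vivo study this package models.  They serve two roles: generating values
for synthetic virtual studies (the raw animal data are not deposited), and
fixed reference points for cross-table consistency checks.

Single oral dose 1 mg/kg; plasma sampled at 5, 15, 30 min and 1, 2, 4, 8,
12, 24 hr; urine collected cumulatively over 0-24 hr.  Group sizes:
control n=6, OY n=4, AB n=5.
"""

GROUPS = ("control", "OY", "AB")

DOSE_MG_PER_KG = 1.0
PLASMA_TIMES_HR = (5 / 60, 15 / 60, 30 / 60, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0)
URINE_INTERVAL_HR = 24.0
GROUP_N = {"control": 6, "OY": 4, "AB": 5}

#: Noncompartmental summary table: parameter -> group -> (mean, sd).
NCA_SUMMARY = {
    "t_half": {"control": (4.10, 2.52), "OY": (3.42, 0.74), "AB": (3.64, 1.33)},
    "tmax": {"control": (0.67, 0.26), "OY": (1.25, 0.50), "AB": (0.45, 0.11)},
    "cmax": {"control": (744.00, 252.96), "OY": (441.50, 63.30), "AB": (831.80, 53.00)},
    "auc_all": {"control": (2042.33, 247.68), "OY": (1899.00, 167.91), "AB": (2144.54, 231.19)},
    "auc_inf": {"control": (2051.75, 259.74), "OY": (1905.79, 168.62), "AB": (2152.10, 233.63)},
    "vz_over_f": {"control": (2.78, 1.32), "OY": (2.60, 0.54), "AB": (2.41, 0.83)},
    "cl_over_f": {"control": (8.23, 1.06), "OY": (8.80, 0.78), "AB": (7.82, 0.85)},
    "fe_urine": {"control": (62.40, 8.56), "OY": (61.08, 5.02), "AB": (61.31, 14.25)},
    "f_pct": {"control": (88.02, 11.14), "OY": (81.76, 7.23), "AB": (92.33, 10.02)},
}

#: Population model estimates: systemic disposition shared across groups,
#: absorption rate constant and bioavailability resolved by pretreatment arm.
#: Each entry is (estimate, relative standard error as a fraction).
POPPK_MEANS = {
    "k12": (0.803, 0.123),
    "k21": (0.965, 0.062),
    "kel": (0.839, 0.112),
    "kel_ur": (0.190, 0.123),
    "vc": (0.448, 0.009),
    "f.control": (0.867, 0.139),
    "f.OY": (0.788, 0.144),
    "f.AB": (0.895, 0.02),
    "ka.control": (1.28, 0.231),
    "ka.OY": (0.523, 0.140),
    "ka.AB": (1.74, 0.076),
}

#: Between-subject variability, CV fraction -> (cv, rse fraction of the CV).
POPPK_BSV_CV = {
    "k12": (0.102, 3.49),
    "k21": (0.045, 3.40),
    "kel": (0.185, 0.42),
    "kel_ur": (0.066, 4.18),
    "vc": (0.013, 6.99),
    "f.control": (0.072, 3.42),
    "f.OY": (0.038, 6.90),
    "f.AB": (0.011, 3.50),
    "ka.control": (0.558, 0.95),
    "ka.OY": (0.161, 1.35),
    "ka.AB": (0.122, 3.17),
}

#: Dose-normalised intravenous AUC reference (ng*hr/mL per mg/kg).  The
#: original analysis took its IV reference from an earlier study without
#: printing it; this value is back-derived from the published control-group
#: oral AUC_inf and absolute bioavailability: 100 * 2051.75 / 88.02.
IV_AUC_REFERENCE = 100.0 * NCA_SUMMARY["auc_inf"]["control"][0] / NCA_SUMMARY["f_pct"]["control"][0]

#: Reported absorption half-lives implied by the Ka estimates (hr).
ABSORPTION_HALF_LIFE_HR = {"control": 0.54, "OY": 1.33}

#: Reported upper bound on the relative error between NCA and model
#: bioavailability across groups (fraction).
F_CROSS_CHECK_MAX_REL_ERROR = 0.0363
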