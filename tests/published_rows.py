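"""Published per-drug characterization rows used as regression inputs.

Each tuple: (drug, mw, logp, psa, hbd, hba, ml_probability, printed ml class,
printed P-gp liability, printed tractability class, printed evidence level,
approved). These small-molecule and peptide candidate rows are transcribed
printed values used as *inputs* to the classification rules; rows whose
printed cells are internally inconsistent with the stated rules are listed in
the exception sets below and asserted as documented exceptions.
"""

SMALL_MOLECULE_ROWS = [
    ("PLERIXAFOR", 502.8, 2.15, 118.4, 8, 12, 0.650, "ModerateHigh", "Moderate", "I", "Mechanistic", True),
    ("PRENYLAMINE", 329.5, 4.26, 38.8, 0, 2, 0.920, "High", "Moderate", "I", "Mechanistic", True),
    ("DULOXETINE", 297.4, 4.23, 44.9, 1, 2, 0.890, "High", "Moderate", "I", "Mechanistic", True),
    ("MEMANTINE", 179.3, 3.28, 26.0, 1, 1, 0.950, "High", "Low", "I", "Established", True),
    ("DONEPEZIL", 379.5, 4.26, 38.8, 0, 3, 0.910, "High", "Moderate", "I", "Established", True),
    ("SERTRALINE", 306.2, 5.29, 12.0, 1, 1, 0.880, "High", "Moderate", "I", "Mechanistic", True),
    ("RISPERIDONE", 410.5, 3.04, 61.8, 0, 5, 0.820, "High", "Moderate", "I", "Mechanistic", True),
    ("QUETIAPINE", 383.5, 2.87, 73.8, 1, 6, 0.750, "ModerateHigh", "Moderate", "I", "Mechanistic", True),
    ("LEVETIRACETAM", 170.2, -0.64, 63.4, 1, 3, 0.780, "ModerateHigh", "Low", "I", "Mechanistic", True),
    ("FLUOXETINE", 309.3, 4.05, 21.3, 1, 2, 0.920, "High", "Moderate", "I", "Mechanistic", True),
    ("TOPIRAMATE", 339.4, 0.89, 118.0, 0, 9, 0.580, "Moderate", "Low", "II", "Mechanistic", True),
    ("GABAPENTIN", 171.2, -1.10, 63.3, 2, 3, 0.720, "ModerateHigh", "Low", "I", "Mechanistic", True),
    ("OLANZAPINE", 312.4, 3.00, 44.0, 1, 4, 0.880, "High", "Moderate", "I", "Mechanistic", True),
    ("CARBAMAZEPINE", 236.3, 2.45, 46.3, 1, 2, 0.910, "High", "Low", "I", "Mechanistic", True),
    ("VALPROATE", 144.2, 2.75, 37.3, 1, 2, 0.930, "High", "Low", "I", "Mechanistic", True),
]

PEPTIDE_ROWS = [
    ("TROFINETIDE", 341.4, 1.89, 45.2, 1, 3, 0.917, "High", "Low", "I", "Speculative", True),
    ("CALCDPWW", 287.4, 1.60, 41.9, 1, 3, 0.917, "High", "Low", "I", "Mechanistic", False),
    ("SOMATOSTATIN", 1638.0, -3.15, 456.2, 18, 26, 0.145, "Low", "High", "III", "Mechanistic", True),
    ("OCTREOTIDE", 1019.2, -0.85, 267.5, 10, 14, 0.320, "Low", "High", "III", "Mechanistic", True),
    ("LANREOTIDE", 1096.4, -1.12, 289.8, 11, 15, 0.295, "Low", "High", "III", "Mechanistic", True),
    ("PASIREOTIDE", 1047.2, -0.98, 279.3, 10, 14, 0.308, "Low", "High", "III", "Mechanistic", True),
    ("VASOACTIVE INT.", 3326.0, -5.89, 892.4, 32, 48, 0.052, "VeryLow", "High", "IV", "Mechanistic", True),
    ("GLUCAGON", 3483.0, -6.12, 945.6, 35, 51, 0.048, "VeryLow", "High", "IV", "Mechanistic", True),
    ("INSULIN LISPRO", 5808.0, -8.45, 1567.0, 52, 78, 0.015, "VeryLow", "High", "IV", "Mechanistic", True),
    ("EXENATIDE", 4186.6, -7.23, 1234.5, 41, 62, 0.025, "VeryLow", "High", "IV", "Mechanistic", True),
]

#: Printed probability band contradicts the stated class-threshold rule.
ML_CLASS_EXCEPTIONS = {"SOMATOSTATIN"}  # 0.145 printed as "Low", band says VeryLow

#: Printed tractability contradicts the stated three-criterion rule.
TRACTABILITY_EXCEPTIONS = {"PLERIXAFOR"}  # MW 502.8 > 450 fails the MW criterion

#: Printed P-gp liability cells contradicting the two-of-three factor rule.
PGP_EXCEPTIONS = {
    "MEMANTINE",     # one factor (LogP 3.28) -> Moderate, printed Low
    "PLERIXAFOR",    # two factors (MW 502.8, HBA 12) -> High, printed Moderate
    "RISPERIDONE",   # two factors (MW 410.5, LogP 3.04) -> High, printed Moderate
    "TOPIRAMATE",    # one factor (HBA 9) -> Moderate, printed Low
    "OLANZAPINE",    # zero factors (LogP 3.00 is not > 3.0) -> Low, printed Moderate
    "QUETIAPINE",    # zero factors -> Low, printed Moderate
}
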