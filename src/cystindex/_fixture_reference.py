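"""Frozen cell-level reference copy of the packaged PCK-rat study table.

The packaged CSV is checked against these rows at load time; a mismatch
raises :class:`~cystindex.errors.FixtureIntegrityError` naming the first
differing cell. Keeping the reference in source makes silent corruption
of the data file detectable.
"""

HEADER = "animal_id,ci_percent,kidney_mass,kidney_body_mass_ratio,ngal_serum,ngal_urine,kim1_urine,cystatin_c_serum,cystatin_c_urine,il18_serum,il18_urine,scr,bun,proteinuria,microalbuminuria"

ROWS = (
    "1,27.58,6.73,1.75,NA,960.00,0.0027,0.57,15.00,0.000034,0.005328081,0.61,36,427.73,72.03",
    "2,30.36,6.75,1.65,3.99,1088.00,0.0027,1.13,3.44,0.000027,0.011396997,0.62,34,489.05,61.37",
    "3,30.92,7.60,1.82,1.54,120.18,0.0029,1.48,14.51,0.000032,0.009516466,0.78,43,434.90,79.92",
    "4,34.49,7.25,1.65,0.86,73.92,0.0033,1.12,7.83,0.000078,0.020001416,0.50,31,527.10,91.84",
    "5,20.93,5.40,1.21,0.71,168.53,0.0025,1.37,9.64,0.000026,0.005473673,0.48,24,563.21,104.99",
    "6,26.24,7.11,1.70,1.18,636.69,0.0030,0.79,13.89,0.000036,0.006371703,0.49,33,409.87,55.15",
    "7,23.77,5.54,1.38,1.28,629.03,0.0044,1.84,14.70,0.000085,0.013753793,0.53,30,782.75,125.10",
    "8,26.09,5.73,1.21,1.05,63.54,0.0028,0.98,21.32,0.000100,0.009541357,0.54,25,618.30,134.45",
    "9,22.02,4.80,1.12,1.05,416.73,0.0048,1.22,24.00,0.000056,0.008970211,0.49,27,562.65,113.03",
    "10,19.83,5.06,1.27,0.82,206.11,0.0034,1.31,0.41,0.000016,0.007020066,0.53,25,389.92,70.40",
    "11,19.67,6.16,1.34,0.97,70.90,0.0048,1.00,16.78,0.000066,0.007412596,0.56,25,799.80,173.22",
    "12,15.47,6.05,1.50,3.06,1216.00,0.0049,1.86,19.45,0.000037,0.005764512,0.58,26,752.99,121.27",
    "13,21.04,8.41,1.98,3.38,NA,NA,1.44,NA,0.000049,NA,0.63,32,NA,NA",
    "14,25.24,7.00,1.94,NA,NA,NA,2.46,NA,0.000134,NA,0.77,44,NA,NA",
    "15,23.76,6.77,1.57,NA,384.00,NA,1.33,3.79,0.000065,0.005986509,0.58,27,143.81,23.82",
    "16,11.59,3.62,0.92,1.92,432.01,NA,1.12,0.28,0.000048,NA,0.38,24,188.85,35.21",
    "17,5.93,3.28,0.84,0.80,39.76,NA,0.97,0.10,0.000019,0.002081549,0.43,22,138.42,30.27",
    "18,0.45,3.49,0.81,0.73,65.88,NA,0.67,2.92,0.000022,NA,0.33,20,307.97,67.96",
    "19,17.36,5.09,1.12,1.08,66.85,NA,0.59,0.18,0.000026,0.00268384,0.47,27,208.96,50.05",
    "20,3.88,4.00,0.94,2.01,381.62,NA,0.68,3.82,0.000056,0.001771726,0.38,19,287.14,47.79",
    "21,7.53,5.30,1.26,1.17,133.07,NA,1.46,0.11,0.000119,0.001387699,0.54,27,147.88,25.64",
    "22,18.96,4.98,1.11,1.78,35.91,NA,1.20,1.46,0.000049,0.002186404,0.52,25,260.17,35.50",
    "23,18.08,5.71,1.41,1.70,355.69,NA,0.55,4.19,0.000074,0.002382867,0.55,28,238.80,31.94",
    "24,16.87,7.74,1.77,1.25,184.60,NA,1.66,7.46,0.000021,0.002955052,0.58,36,292.41,36.66",
    "25,13.71,5.61,1.22,1.21,40.07,NA,NA,0.25,0.000062,0.0019058,0.56,25,215.03,41.81",
    "26,10.65,4.52,1.07,1.44,300.97,NA,0.88,8.15,0.000032,0.002226449,0.38,22,252.14,61.53",
    "27,12.03,5.94,1.21,1.24,NA,NA,NA,NA,0.000025,NA,0.46,25,NA,NA",
)
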