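"""Synthetic stand-in residue descriptor scales.

These tables fill the 8-, 6- and 3-component descriptor slots of the feature
encoder (the roles played by the ProtFP, FASGAI and Cruciani scales).  They
are NOT the published values: they are synthetic stand-ins generated by
standardized PCA of RDKit 2D descriptors of the 20 free amino acids (see
scripts/derive_scales.py).  Users with access to the published tables can
substitute them via DescriptorTables.

Auto-generated; do not edit by hand.
"""

SYNTHETIC_PCP8 = {
    "A": (-7.7961, -3.5959, -1.0344,  0.8071,  0.6575,  2.6603,  0.6018, -1.3032),
    "C": (-5.6467, -2.8173,  0.6508, -3.3467,  4.8771, -4.0916, -3.8678,  1.0954),
    "D": (-3.1162,  6.9474, -4.8629,  2.1296, -2.4943, -2.1404, -2.4828,  0.5005),
    "E": (-0.4520,  6.5060, -2.7411,  1.8880, -2.1599, -1.3286, -2.1005,  2.7207),
    "F": ( 6.8957, -3.4828, -0.0675,  2.7617, -0.0864,  2.8638, -2.7476, -1.0135),
    "G": (-11.1663, -4.6848, -2.9599, -2.6425,  4.0642,  7.0812,  0.1496,  1.4588),
    "H": ( 5.5307, -1.7986, -5.3164, -7.6102, -0.5041, -1.2511,  4.1038, -1.3348),
    "I": ( 0.1700, -2.6344,  4.0369,  2.7028, -3.5991,  0.7920, -0.6984, -0.9976),
    "K": ( 1.6665,  1.5964,  5.4381, -0.5789, -0.3960,  0.3619,  1.1885, -0.7024),
    "L": (-0.2655, -2.3818,  4.6051,  2.4662, -2.6871,  1.7375, -0.9453, -1.3999),
    "M": (-0.1944, -3.1396,  4.8521, -2.2004,  3.8599, -5.3374, -4.0747,  1.4887),
    "N": (-2.5640,  6.6548, -1.9472, -0.8496, -0.9500,  1.7603, -0.7386,  2.2508),
    "P": (-1.2007, -8.5948,  0.1340, -0.1985, -5.1429, -3.3435,  5.3334,  5.9330),
    "Q": ( 0.0232,  6.8882,  0.0585, -0.5388, -1.1295,  1.9520, -0.7182,  3.4184),
    "R": ( 4.5235,  8.9535,  7.0532, -5.2045,  2.3304,  1.6150,  4.0766, -0.8054),
    "S": (-6.6282,  0.8011, -2.8486,  0.0316,  0.7657, -2.2648,  1.6003, -4.6560),
    "T": (-4.1655,  1.3515, -1.5658,  2.1245, -1.2642, -3.5491,  1.8027, -5.6401),
    "V": (-2.4692, -2.4000,  2.6679,  3.0471, -2.1927,  1.4134, -0.3979, -1.0744),
    "W": ( 16.8118, -4.1647, -3.7389, -3.7626, -1.7016,  1.6843, -3.9519, -1.5408),
    "Y": ( 10.0436, -0.0043, -2.4138,  8.9741,  7.7529, -0.6153,  3.8669,  1.6019),
}

SYNTHETIC_PCP6 = {
    "A": (-7.7961, -3.5959, -1.0344,  0.8071,  0.6575,  2.6603),
    "C": (-5.6467, -2.8173,  0.6508, -3.3467,  4.8771, -4.0916),
    "D": (-3.1162,  6.9474, -4.8629,  2.1296, -2.4943, -2.1404),
    "E": (-0.4520,  6.5060, -2.7411,  1.8880, -2.1599, -1.3286),
    "F": ( 6.8957, -3.4828, -0.0675,  2.7617, -0.0864,  2.8638),
    "G": (-11.1663, -4.6848, -2.9599, -2.6425,  4.0642,  7.0812),
    "H": ( 5.5307, -1.7986, -5.3164, -7.6102, -0.5041, -1.2511),
    "I": ( 0.1700, -2.6344,  4.0369,  2.7028, -3.5991,  0.7920),
    "K": ( 1.6665,  1.5964,  5.4381, -0.5789, -0.3960,  0.3619),
    "L": (-0.2655, -2.3818,  4.6051,  2.4662, -2.6871,  1.7375),
    "M": (-0.1944, -3.1396,  4.8521, -2.2004,  3.8599, -5.3374),
    "N": (-2.5640,  6.6548, -1.9472, -0.8496, -0.9500,  1.7603),
    "P": (-1.2007, -8.5948,  0.1340, -0.1985, -5.1429, -3.3435),
    "Q": ( 0.0232,  6.8882,  0.0585, -0.5388, -1.1295,  1.9520),
    "R": ( 4.5235,  8.9535,  7.0532, -5.2045,  2.3304,  1.6150),
    "S": (-6.6282,  0.8011, -2.8486,  0.0316,  0.7657, -2.2648),
    "T": (-4.1655,  1.3515, -1.5658,  2.1245, -1.2642, -3.5491),
    "V": (-2.4692, -2.4000,  2.6679,  3.0471, -2.1927,  1.4134),
    "W": ( 16.8118, -4.1647, -3.7389, -3.7626, -1.7016,  1.6843),
    "Y": ( 10.0436, -0.0043, -2.4138,  8.9741,  7.7529, -0.6153),
}

SYNTHETIC_PCP3 = {
    "A": (-7.7961, -3.5959, -1.0344),
    "C": (-5.6467, -2.8173,  0.6508),
    "D": (-3.1162,  6.9474, -4.8629),
    "E": (-0.4520,  6.5060, -2.7411),
    "F": ( 6.8957, -3.4828, -0.0675),
    "G": (-11.1663, -4.6848, -2.9599),
    "H": ( 5.5307, -1.7986, -5.3164),
    "I": ( 0.1700, -2.6344,  4.0369),
    "K": ( 1.6665,  1.5964,  5.4381),
    "L": (-0.2655, -2.3818,  4.6051),
    "M": (-0.1944, -3.1396,  4.8521),
    "N": (-2.5640,  6.6548, -1.9472),
    "P": (-1.2007, -8.5948,  0.1340),
    "Q": ( 0.0232,  6.8882,  0.0585),
    "R": ( 4.5235,  8.9535,  7.0532),
    "S": (-6.6282,  0.8011, -2.8486),
    "T": (-4.1655,  1.3515, -1.5658),
    "V": (-2.4692, -2.4000,  2.6679),
    "W": ( 16.8118, -4.1647, -3.7389),
    "Y": ( 10.0436, -0.0043, -2.4138),
}
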