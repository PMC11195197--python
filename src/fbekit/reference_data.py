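"""Published reference measurements used as fixtures and ground truths.

These are the *gld-1* RNA sequences and the measured FBF-2/LST-1 binding
parameters (ITC one-set-of-sites fits and EMSA Kd's) that the synthetic
generators use as generating truths and the worked examples reproduce.
Energies are kJ/mol, Kd units as annotated, temperatures kelvin.
"""

from __future__ import annotations

from dataclasses import dataclass

#: 29-nt *gld-1* fragment carrying the tandem FBEa and FBEa* elements.
GLD1_FBEA_FBEASTAR_RNA = "AUCAUGUGCCAUACAUCAUGUUGCCAUUU"

#: 11-nt FBEa* RNA used for crystallography.
GLD1_FBEASTAR_11NT = "CAUGUUGCCAU"

#: Core elements within the 29-nt fragment (0-based starts).
GLD1_FBEA_CORE = "UGUGCCAUA"        # canonical FBE at offset 4
GLD1_FBEASTAR_CORE = "UGUUGCCAUU"   # 10-nt FBEa*-like at offset 18

#: Flank-inclusive element forms (upstream-C convention): 11-nt FBEa
#: CAUGUGCCAUA at offset 2 and 12-nt FBEa* CAUGUUGCCAUU at offset 16,
#: giving the narrative 3-nt spacing; the core-element formula gives 5.
GLD1_FBEA_FLANKED = "CAUGUGCCAUA"
GLD1_FBEASTAR_FLANKED = "CAUGUUGCCAUU"

#: Assay temperature for the calorimetry experiments (20 degC).
ITC_TEMPERATURE_K = 293.15


@dataclass(frozen=True)
class ITCReferenceLine:
    """One ITC measurement line: FBF-2 variant vs LST-1 variant.

    Two technical replicates per line; ``n_sites``/``kd_um``/``delta_h``
    are the per-replicate best-fit values, ``delta_g``/``minus_tds`` the
    printed derived columns (kJ/mol).  Kd in micromolar.
    """

    line: int
    fbf2: str
    lst1: str
    wt_pims: str
    n_sites: tuple[float, float]
    kd_um: tuple[float, float]
    delta_h: tuple[float, float]
    delta_g: tuple[float, float]
    minus_tds: tuple[float, float]


#: Measured one-set-of-sites ITC parameters (lines with detected binding).
ITC_REFERENCE: dict[int, ITCReferenceLine] = {
    1: ITCReferenceLine(1, "RBD+CT", "LST-1(19-98)", "A+B",
                        (0.50, 0.57), (1.1, 1.9), (-61.9, -45.1),
                        (-33.4, -32.1), (28.5, 13.0)),
    2: ITCReferenceLine(2, "RBD+CT", "LST-1(19-98)(Am)", "B",
                        (1.02, 0.98), (2.8, 3.7), (-47.9, -48.3),
                        (-31.2, -30.5), (16.7, 17.8)),
    3: ITCReferenceLine(3, "RBD+CT", "LST-1(19-98)(Bm)", "A",
                        (1.06, 0.89), (24.1, 46.2), (-46.3, -48.3),
                        (-25.9, -24.4), (20.3, 23.9)),
    5: ITCReferenceLine(5, "RBD", "LST-1(19-98)", "A+B",
                        (0.46, 0.46), (0.48, 0.52), (-139.0, -157.0),
                        (-35.5, -35.3), (104.0, 122.0)),
    6: ITCReferenceLine(6, "RBD", "LST-1(19-98)(Am)", "B",
                        (1.15, 1.05), (0.13, 0.12), (-64.1, -68.9),
                        (-38.7, -38.9), (25.4, 30.0)),
    7: ITCReferenceLine(7, "RBD", "LST-1(19-98)(Bm)", "A",
                        (0.83, 0.86), (1.46, 1.54), (-50.8, -52.5),
                        (-32.8, -32.6), (18.0, 19.9)),
}


@dataclass(frozen=True)
class EMSAReferenceRow:
    """One EMSA measurement: protein, RNA, mean Kd +/- SEM in nM.

    ``kd_nm`` is None when binding was undetectable; ``kd_is_bound`` marks
    '>' style lower bounds where Kd exceeded the tested protein range.
    """

    protein: str
    rna: str
    fbes_intact: str
    lst1: str
    replicates: int
    kd_nm: float | None
    sem_nm: float | None = None
    kd_is_bound: bool = False


#: Measured EMSA affinities for the 29-nt FBEa-FBEa* RNA and mutants.
EMSA_REFERENCE: list[EMSAReferenceRow] = [
    EMSAReferenceRow("RBD+CT", "FBEa-FBEa*", "a a*", "none", 3, 435.0, 44.0),
    EMSAReferenceRow("RBD", "FBEa-FBEa*", "a a*", "none", 4, 131.0, 20.0),
    EMSAReferenceRow("RBD+CT L610A", "FBEa-FBEa*", "a a*", "none", 4, 80.0, 21.0),
    EMSAReferenceRow("RBD+CT", "FBEa-FBEa*m", "a", "none", 3, 1190.0, 15.0),
    EMSAReferenceRow("RBD+CT", "FBEam-FBEa*", "a*", "none", 3, 5000.0, None, True),
    EMSAReferenceRow("RBD+CT", "FBEam-FBEa*m", "none", "none", 3, 2500.0, None, True),
    EMSAReferenceRow("RBD+CT", "FBEa-FBEa*", "a a*", "19-98", 3, 109.0, 4.0),
    EMSAReferenceRow("RBD", "FBEa-FBEa*m", "a", "none", 4, 145.0, 7.0),
    EMSAReferenceRow("RBD", "FBEam-FBEa*", "a*", "none", 3, 323.0, 34.0),
    EMSAReferenceRow("RBD", "FBEam-FBEa*m", "none", "none", 3, None),
    EMSAReferenceRow("RBD", "FBEa-FBEa*", "a a*", "19-98", 3, 107.0, 6.0),
]

#: Single-element FBEa* EMSA affinities (14-nt RNA), nM.
EMSA_FBEASTAR_RBD_KD_NM = 427.0
#: Previously reported RBD affinity for FBEa alone, nM.
EMSA_FBEA_RBD_KD_NM = 70.0
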