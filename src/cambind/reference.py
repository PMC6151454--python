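"""Published study inputs for the calmodulin/calcineurin-peptide system.

These are the printed experimental quantities the analyses consume:
the calcineurin CaM-target peptide sequence with its author numbering,
the anchor residues defining the 1-5-15-18 spacing, the calmodulin domain
windows, the DLS size standards, and the measured hydrodynamic radius of
the complex.  Keeping them here lets every analysis (and the reproduction
script) run without any external download.
"""

from .biophys_calibration import CalibrationPoint

# calcineurin-A CaM-target peptide (CaNp), author numbering 391-414
CANP_SEQUENCE = "ARKEVIRNKIRAIGKMARVFSVLR"
CANP_START = 391
CANP_END = 414
CANP_KINK_RESIDUE = 404  # the Gly tether between the two helical segments
CANP_HELICAL_RANGE = (392, 413)  # helical upon binding

# hydrophobic anchors of CaNp (author numbering); 396/413 are the major pair
CANP_ANCHORS = (396, 400, 410, 413)
CANP_MAJOR_ANCHORS = (396, 413)

# calmodulin windows (author numbering)
CAM_N_DOMAIN = (5, 72)
CAM_C_DOMAIN = (84, 145)
CAM_ORDERED_RANGE = (5, 145)
CAM_LENGTH = 148
EF_HAND_OFFSET = 73  # pairs N-domain residue i with homologous C-domain i+73

# intermolecular salt bridges: (peptide residue, calmodulin residue)
SALT_BRIDGE_PAIRS = ((392, 47), (393, 54), (408, 84), (414, 114))

# DLS calibration standards: (label, R_H in nm, M_r in kDa)
DLS_STANDARDS = (
    CalibrationPoint(r_h=6.75, m_r=67.0, label="BSA"),
    CalibrationPoint(r_h=2.44, m_r=16.7, label="calmodulin"),
    CalibrationPoint(r_h=2.20, m_r=14.7, label="lysozyme"),
    CalibrationPoint(r_h=1.70, m_r=8.4, label="ubiquitin"),
)
COMPLEX_RH_NM = 2.61  # measured hydrodynamic radius of the 1:1 complex

# CD: helical residue count of the bound peptide implied by the two-state
# estimate (17 of 24 residues ≈ 71%)
BOUND_HELIX_RESIDUES = 17
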