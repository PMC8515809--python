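# Karplus coefficient registry: J(theta) = A*cos^2(theta + delta) + B*cos(theta + delta) + C
#
# A, B, C and sigma (the parametrization error used in the chi^2 score)
# are in Hz; delta is in degrees.  The selector names the backbone
# torsion the coupling reports on: "phi" and "psi" use the torsion of the
# coupled residue itself, "psi_prev" the psi of the preceding residue.
#
# These are shipped defaults taken from the standard literature
# parametrizations named in each citation tag; they are data, not code,
# and can be replaced wholesale with load_karplus_registry(path).
couplings:
  - type: 3JHNHa
    A: 7.09
    B: -1.42
    C: 1.55
    delta: -60.0
    sigma: 0.91
    selector: phi
    citation: "Hu & Bax, J. Am. Chem. Soc. 119 (1997)"
  - type: 3JHaC'
    A: 3.72
    B: -2.18
    C: 1.28
    delta: 120.0
    sigma: 0.38
    selector: phi
    citation: "Hu & Bax, J. Am. Chem. Soc. 119 (1997)"
  - type: 3JHNC'
    A: 4.29
    B: -1.01
    C: 0.00
    delta: 180.0
    sigma: 0.59
    selector: phi
    citation: "Hu & Bax, J. Am. Chem. Soc. 119 (1997)"
  - type: 3JHNCb
    A: 3.06
    B: -0.74
    C: 0.13
    delta: 60.0
    sigma: 0.39
    selector: phi
    citation: "Hu & Bax, J. Am. Chem. Soc. 119 (1997)"
  - type: 1JNCa
    A: 1.70
    B: -0.98
    C: 9.51
    delta: 0.0
    sigma: 0.59
    selector: psi
    citation: "Wirmer & Schwalbe, J. Biomol. NMR 23 (2002)"
  - type: 2JNCa
    A: -0.66
    B: -1.52
    C: 7.85
    delta: 0.0
    sigma: 0.50
    selector: psi_prev
    citation: "Ding & Gronenborn, J. Am. Chem. Soc. 126 (2004)"
  - type: 3JHNCa
    A: -0.23
    B: -0.20
    C: 0.97
    delta: 0.0
    sigma: 0.10
    selector: psi_prev
    citation: "Hennig et al., J. Am. Chem. Soc. 122 (2000)"
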