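"""Regenerate the embedded emission-line catalogue from xraylib.

Development-time only: xraylib is not a runtime dependency.  The output CSV
is committed at src/xrflabel/data/emission_lines.csv.

Usage: python scripts/build_line_table.py > src/xrflabel/data/emission_lines.csv
"""

import re

import xraylib as xl

K_ELEMENTS = ["P", "S", "Cl", "K", "Ca", "Ti", "V", "Cr", "Mn",
              "Fe", "Co", "Ni", "Cu", "Zn"]
L_ELEMENTS = ["La", "Ce", "Pr", "Nd", "Pm", "Sm", "Eu", "Gd", "Tb",
              "Dy", "Ho", "Er", "Tm", "Yb", "Lu"]

SHELL_OF = {"K": xl.K_SHELL, "L1": xl.L1_SHELL, "L2": xl.L2_SHELL,
            "L3": xl.L3_SHELL}


def lines_for(symbol, series):
    z = xl.SymbolToAtomicNumber(symbol)
    if series == "K":
        pat = r"^K[LMNOPQ]\d_LINE$"
        eref = xl.EdgeEnergy(z, xl.K_SHELL) + 1.0
    else:
        pat = r"^L[123][LMNOPQ]\d_LINE$"
        eref = xl.EdgeEnergy(z, xl.L1_SHELL) + 1.0
    rows = []
    for name in sorted(dir(xl)):
        if not re.match(pat, name):
            continue
        code = getattr(xl, name)
        transition = name[:-5]
        shell = transition[:2] if transition.startswith("L") else "K"
        try:
            energy = xl.LineEnergy(z, code)
            # Kissel cascade cross sections weight L subshells correctly
            # relative to one another at the reference excitation.
            strength = xl.CS_FluorLine_Kissel_Cascade(z, code, eref)
        except Exception:
            continue
        if energy <= 0 or strength <= 0:
            continue
        edge = xl.EdgeEnergy(z, SHELL_OF[shell])
        rows.append([symbol, transition, energy, strength, edge, series])
    top = max(r[3] for r in rows)
    for r in rows:
        r[3] = r[3] / top
    rows.sort(key=lambda r: -r[3])
    return rows


def main():
    print("element,transition,energy_keV,rel_intensity,edge_keV,series")
    for sym in K_ELEMENTS:
        for r in lines_for(sym, "K"):
            print(f"{r[0]},{r[1]},{r[2]:.5f},{r[3]:.6g},{r[4]:.5f},{r[5]}")
    for sym in L_ELEMENTS:
        for r in lines_for(sym, "L"):
            print(f"{r[0]},{r[1]},{r[2]:.5f},{r[3]:.6g},{r[4]:.5f},{r[5]}")


if __name__ == "__main__":
    main()
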