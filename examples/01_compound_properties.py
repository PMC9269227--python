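"""Molecular properties and ESI-MS identity checks for the query set.

Each bundled cannabinoid's nominal [M+H]+ (integer isotope masses + 1) is
compared with its recorded positive-mode ESI-MS peak; the remaining
columns are the descriptors used for decoy matching.
"""

from ivscreen import QUERY_COMPOUNDS, compute_properties, validate_identity

EXPECTED_MZ = {"cbt1": 331, "cbd": 315, "cbda": 359}

print(f"{'id':6} {'formula':10} {'MW':>7} {'[M+H]+':>7} {'HBD':>4} {'HBA':>4} "
      f"{'rot':>4}  identity")
for c in QUERY_COMPOUNDS:
    p = compute_properties(c)
    ok = validate_identity(c, EXPECTED_MZ[c.id])
    print(f"{c.id:6} {c.formula:10} {p.mw:7.2f} {p.mz_protonated:7d} "
          f"{p.hbd:4d} {p.hba:4d} {p.n_rot:4d}  "
          f"{'matches m/z %d' % EXPECTED_MZ[c.id] if ok else 'MISMATCH'}")

print("\nA matching [M+H]+ confirms the encoded structure has the mass the "
      "isolated compound showed.")
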