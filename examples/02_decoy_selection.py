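"""Ten-decoy selection for CBD from a generated candidate library.

Decoys must resemble the query in MW/HBD/HBA (within +-25 Da / +-1 / +-1)
while being structurally dissimilar (Tanimoto < 0.4), so they probe how
well each target binds *generic* molecules of this size and polarity.
"""

from ivscreen import QUERY_COMPOUNDS, compute_properties, select_decoys, tanimoto
from ivscreen.synth import generate_decoy_library

query = next(c for c in QUERY_COMPOUNDS if c.id == "cbd")
qp = compute_properties(query)
library = generate_decoy_library(qp.mw, qp.hbd, qp.hba, n_candidates=50, seed=0)
decoys = select_decoys(query, library, n=10)

print(f"query {query.id}: MW {qp.mw:.1f}, HBD {qp.hbd}, HBA {qp.hba}")
print(f"{len(library)} candidates -> {len(decoys.decoys)} decoys:")
for d in decoys.decoys:
    dp = compute_properties(d)
    print(f"  {d.id}  MW {dp.mw:7.2f}  HBD {dp.hbd}  HBA {dp.hba}  "
          f"Tanimoto {tanimoto(query, d):.2f}")
print("\nAll ten sit inside the matching windows with low similarity — "
      "property twins, structural strangers.")
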