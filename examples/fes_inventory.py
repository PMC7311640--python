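"""Iron-sulfur cluster inventory and predicted iron stoichiometry.

Plants a synthetic subunit carrying the full HydAB-heterodimer cluster
complement — five [4Fe-4S], two [2Fe-2S] and one H-cluster — scans it with
the cysteine-spacing motif grammar, and totals the implied iron content.
"""

from hydbeta import (
    annotations_to_table,
    make_reference_scaffold,
    plant_sequence,
    predicted_iron_content,
    scan_clusters,
)
from hydbeta.fescan import FES2, FES4, HCLUSTER

scaffold = make_reference_scaffold(seed=1)
rec, truth = plant_sequence(
    scaffold, "BF", background_identity=0.8, seed=42,
    cluster_counts={FES4: 5, FES2: 2, HCLUSTER: 1},
)

annotations = scan_clusters(rec)
print(annotations_to_table(annotations).to_string(index=False))
print()
iron = predicted_iron_content(annotations)
print(f"predicted iron content: {iron} Fe per subunit complement")
print()
print("Reading: 5x4 + 2x2 + 6 = 30 iron atoms — the predicted stoichiometry")
print("for one alpha-beta heterodimer, to be compared against a measured")
print("iron content (e.g. ferrozine assay) per mole of complex.")
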