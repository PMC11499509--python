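"""Read and write multi-label datasets as MEKA-style ARFF and CSV.

The ARFF relation name carries the label count in the "-C q" token and the
label attributes come first (nominal {0,1}); the CSV route designates
label columns by name. Both round-trip exactly.
"""

import tempfile
from pathlib import Path

from mltlsmote import load_arff, load_csv, save_arff, save_csv
from mltlsmote.synthetic import frailty_like_preset, generate_mld

mld = generate_mld(frailty_like_preset(200, seed=8))
tmp = Path(tempfile.mkdtemp())

arff_path = tmp / "cohort.arff"
save_arff(mld, arff_path)
back = load_arff(arff_path)  # label count parsed from the "-C 6" token
print(f"ARFF round-trip identical: {back.equals(mld)}")
print("relation line:", arff_path.read_text().splitlines()[0])

csv_path = tmp / "cohort.csv"
save_csv(mld, csv_path)
back = load_csv(csv_path, list(mld.label_names))
print(f"CSV round-trip identical: {back.equals(mld)}")
print(f"{back.n_instances} instances, {back.n_labels} labels, "
      f"{back.n_features} features")
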