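"""Classify the packaged 64-metabolite fixture with the group rules.

Runs the diagnostic-ion / neutral-loss rule engine in nominal (±0.5 Da)
mode over the 40 alkaloid spectra characterized in elicited Camptotheca
acuminata plantlets, then checks each classified compound against the
25-entry registry of previously known camptothecin analogs.
"""

from camptomine.fixture import alkaloid_spectra, paper_fixture
from camptomine.fragrules import annotate

spectra, registry = paper_fixture()
alkaloids = alkaloid_spectra(spectra)

table = annotate(alkaloids, registry, mode="nominal")

print(table[["spectrum_id", "precursor_mz", "primary_group", "score",
             "tags", "novel"]].to_string(index=False))
print()
print(f"classified : {int(table.primary_group.notna().sum())} of "
      f"{len(alkaloids)} alkaloid spectra")
print(f"groups     : {table.primary_group.value_counts().to_dict()}")
print(f"novel      : {int(table.novel.sum())} "
      "(no same-group registry compound within 2 ppm)")

# The group tally (11 CG / 6 PG / 5 SG / 12 VG / 6 VC) is the series
# breakdown of the 40 identified alkaloids; the 15 novel compounds are the
# ones whose precursor mass matches no previously characterized compound
# of the same structural series.
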