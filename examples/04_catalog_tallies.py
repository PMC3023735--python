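"""Tally the shipped soybean-seed target catalogs.

The package carries the source study's published degradome target catalogs
(validated cleavage targets of annotated and newly discovered miRNAs) as
versioned TSV fixtures. This prints the headline counts: total targets per
catalog, the Class I-IV composition, conserved vs soybean-specific family
split, and the most promiscuous conserved miRNA.
"""

from mirslice.fixtures import load_fixture, parse_sites, summarize_fixture

known = load_fixture("known_mirna_targets")
novel = load_fixture("novel_mirna_targets")

print("targets of annotated miRNAs :", summarize_fixture(known))
print("targets of novel miRNAs     :", summarize_fixture(novel))
print("class composition (known)   :", summarize_fixture(known, group_by="class"))
print("conserved-family targets    :", summarize_fixture(known, where=lambda r: r["specific_family"] == 0))
print("specific-family targets     :", summarize_fixture(known, where=lambda r: r["specific_family"] == 1))
by_mirna = summarize_fixture(known, group_by="mirna")
top = max(by_mirna, key=by_mirna.get)
print(f"most promiscuous miRNA      : {top} ({by_mirna[top]} targets)")
dual = [s for s in known["cleavage_site"] if len(parse_sites(s)) > 1]
print("dual-site target rows       :", len(dual))
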