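"""Rank cholinesterase screens: extracts and isolated compounds.

Loads the packaged screen summaries (mean +/- SEM percent inhibition)
and ranks agents per enzyme; 'not detected' entries are excluded rather
than scored as zero, and the positive-control inhibitor is kept out of
the ranking.
"""

from saposcreen import rank_agents, read_screen_table, screen_results

extracts = rank_agents(screen_results(read_screen_table("extract_screen"), "BuChE"))
print("Top crude extracts (BuChE inhibition at 1 mg/mL):")
for r in extracts[:3]:
    print(f"  {r.agent_id:30s} {r.display()} %")

compounds = rank_agents(screen_results(read_screen_table("compound_screen"), "BuChE"))
print("\nTop isolated compounds (BuChE inhibition at 0.1 mg/mL):")
for r in compounds[:3]:
    print(f"  compound {r.agent_id:20s} {r.display()} %")
# The ethyl acetate / ultrasonic extract leads the extract screen and
# compound 3 dominates the compound screen - the two selection decisions
# a bioactivity-guided isolation campaign is built on.
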