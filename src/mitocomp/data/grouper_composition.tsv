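# Published whole-genome base compositions (% of genome), genome sizes and
# strand-asymmetry skews for 22 grouper (Epinephelidae) mitochondrial
# genomes.  AT-skew = (A-T)/(A+T); GC-skew = (G-C)/(G+C), printed at 2 d.p.
species	genome_size_bp	A	T	G	C	at_skew	gc_skew
Aethaloperca rogaa	16538	29.4	27.3	15.9	27.4	0.04	-0.27
Anyperodon leucogrammicus	16616	28.7	26.9	15.7	28.7	0.03	-0.29
Cephalopholis argus	16767	29.2	27.7	16.2	26.9	0.03	-0.25
Cephalopholis sonnerati	16587	29.6	26.2	15.9	28.3	0.06	-0.28
Cromileptes altivelis	16504	29.1	26.3	15.7	29.0	0.05	-0.30
Epinephelus akaara	16795	28.7	27.3	16.2	27.8	0.03	-0.26
Epinephelus areolatus	16965	28.7	27.1	16.3	28.0	0.03	-0.26
Epinephelus awoara	16802	28.5	27.3	16.5	27.7	0.02	-0.25
Epinephelus bruneus	16692	28.5	26.6	16.2	28.7	0.03	-0.28
Epinephelus coioides	16418	28.7	26.5	15.8	28.9	0.04	-0.29
Epinephelus epistictus	16927	29.2	27.0	15.7	28.1	0.04	-0.28
Epinephelus fuscoguttatus	16648	29.2	26.9	15.6	28.3	0.04	-0.29
Epinephelus lanceolatus	16714	29.5	26.5	15.1	28.8	0.05	-0.31
Epinephelus moara	16696	28.6	26.5	16.1	28.9	0.04	-0.28
Epinephelus trimaculatus	16777	29.0	27.1	15.9	28.0	0.03	-0.27
Hyporthodus octofasciatus	16545	28.6	27.4	16.3	27.8	0.02	-0.26
Hyporthodus septemfasciatus	16558	28.6	26.8	16.3	28.3	0.03	-0.27
Plectropomus areolatus	16770	28.8	27.6	16.3	27.2	0.02	-0.25
Plectropomus leopardus	16753	29.1	28.0	16.2	26.7	0.02	-0.24
Triso dermopterus	16605	28.2	25.7	16.7	29.4	0.05	-0.28
Variola albimarginata	16768	28.4	27.7	16.4	27.6	0.01	-0.26
Variola louti	16770	28.4	27.8	16.3	27.5	0.01	-0.26
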