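# Presence/absence of the 23 conserved miRNA families across the eight major land-plant
# groups, reconstructed from the published distribution grid and the censuses stated in
# the accompanying text:
#   - miR156/159/160/166/171/319/408: present in all groups
#   - miR396 absent from mosses; miR167 absent from liverworts and lycophytes
#   - miR390/miR395/miR530-1030/miR535 absent from lycophytes; miR535 moss cell set
#     absent and miR167 moss cell set present so the moss∩fern census equals 15
#   - miR162/168/169/172/403 restricted to ferns + seed plants (euphyllophytes);
#     miR403 additionally absent from basal angiosperms; miR529 absent from eudicots
#   - miR477 absent from liverworts (moss-derived family); its seed-plant cells are a
#     transcription choice that affects no census or origin placement
#   - miR536: liverworts+mosses+ferns; miR1024: mosses+ferns;
#     miR1083: lycophytes+ferns+gymnosperms
family	liverworts	mosses	lycophytes	ferns	gymnosperms	basal_angiosperms	monocots	eudicots
miR156	1	1	1	1	1	1	1	1
miR159	1	1	1	1	1	1	1	1
miR160	1	1	1	1	1	1	1	1
miR162	0	0	0	1	1	1	1	1
miR166	1	1	1	1	1	1	1	1
miR167	0	1	0	1	1	1	1	1
miR168	0	0	0	1	1	1	1	1
miR169	0	0	0	1	1	1	1	1
miR171	1	1	1	1	1	1	1	1
miR172	0	0	0	1	1	1	1	1
miR319	1	1	1	1	1	1	1	1
miR390	1	1	0	1	1	1	1	1
miR395	1	1	0	1	1	1	1	1
miR396	1	0	1	1	1	1	1	1
miR403	0	0	0	1	1	0	1	1
miR408	1	1	1	1	1	1	1	1
miR477	0	1	0	1	1	0	0	1
miR529	1	1	1	1	1	1	1	0
miR530/1030	1	1	0	1	1	1	1	1
miR535	1	0	0	1	1	1	1	1
miR536	1	1	0	1	0	0	0	0
miR1024	0	1	0	1	0	0	0	0
miR1083	0	0	1	1	1	0	0	0
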