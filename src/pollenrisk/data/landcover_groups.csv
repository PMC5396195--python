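code,name,group
1,corn,agricultural
5,soybeans,agricultural
21,barley,agricultural
24,winter_wheat,agricultural
27,rye,agricultural
28,oats,agricultural
36,alfalfa,agricultural
37,other_hay,agricultural
39,buckwheat,agricultural
42,dry_beans,agricultural
43,potatoes,agricultural
54,tomatoes,agricultural
66,cherries,agricultural
68,apples,apple
69,grapes,agricultural
70,christmas_trees,agricultural
205,triticale,agricultural
222,squash,agricultural
229,pumpkins,agricultural
243,cabbage,agricultural
244,cauliflower,agricultural
29,millet,agricultural
49,onions,agricultural
50,cucumbers,agricultural
53,peas,agricultural
206,carrots,agricultural
221,strawberries,agricultural
246,turnips,agricultural
227,lettuce,agricultural
6,sunflower,agricultural
4,sorghum,agricultural
58,clover_wildflowers,natural
61,fallow_idle,natural
121,developed_open,natural
122,developed_low,natural
141,deciduous_forest,natural
142,evergreen_forest,natural
143,mixed_forest,natural
152,shrubland,natural
176,grassland_pasture,natural
190,woody_wetlands,natural
195,herbaceous_wetlands,natural
111,open_water,other
123,developed_medium,other
124,developed_high,other
131,barren,other
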