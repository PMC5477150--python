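column,brand,geometry
col1,Discovery C18,4.6 mm x 250 mm x 5 um
col2,Discovery C18,4.6 mm x 150 mm x 5 um
col3,Xbridge C18,4.6 mm x 250 mm x 5 um
col4,BDS Hypersil C18,4.6 mm x 250 mm x 5 um
col5,Inertsil ODS-2,4.6 mm x 250 mm x 5 um
col6,Kromasil C18,4.6 mm x 250 mm x 5 um
col7,Luna C18(2),4.6 mm x 250 mm x 5 um
col8,Luna C18(2),4.6 mm x 150 mm x 5 um
col9,Inertsil ODS-3,4.6 mm x 150 mm x 5 um
col10,Alltima C18,4.6 mm x 250 mm x 5 um
col11,Symmetry C18,4.6 mm x 250 mm x 5 um
col12,Gemini C18,4.6 mm x 250 mm x 5 um
col13,Capcellpak C18 MG,4.6 mm x 250 mm x 5 um
col14,Zorbax Extend-C18,4.6 mm x 250 mm x 5 um
col15,Sunfire C18,4.6 mm x 250 mm x 5 um
col16,Sunfire C18,4.6 mm x 150 mm x 5 um
col17,Nucleosil C18 HD,4.6 mm x 250 mm x 5 um
col18,ODS Hypersil,4.6 mm x 250 mm x 5 um
col19,Capcellpak C18 AQ,4.6 mm x 250 mm x 5 um
col20,Spherisorb ODS2,4.6 mm x 250 mm x 5 um
col21,Zorbax SB-C18,4.6 mm x 250 mm x 5 um
col22,Diamonsil C18,4.6 mm x 250 mm x 5 um
col23,Diamonsil C18,4.6 mm x 150 mm x 5 um
col24,Diamonsil C18(2),4.6 mm x 250 mm x 5 um
col25,Kromasil Eternity C18,4.6 mm x 250 mm x 5 um
col26,Shim-pack VP-ODS,4.6 mm x 150 mm x 5 um
col27,Agilent HC-C18,4.6 mm x 250 mm x 5 um
col28,Agilent TC-C18,4.6 mm x 250 mm x 5 um
col29,Venusil MP C18,4.6 mm x 150 mm x 5 um
col30,Nucleosil C18 AB,4.6 mm x 250 mm x 5 um
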