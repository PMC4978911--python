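name,label,group,ploidy,Ge_x1e7_sites,Gc_plus_Gnc_x1e7_sites,u_id_x1e-10_per_site_per_gen,u_bs_x1e-10_per_site_per_gen,diversity_value,diversity_type,Ne_printed_x1e6,ne_flagged
Agrobacterium tumefaciens,Agt,bacteria,haploid,0.50,0.57,0.30,2.92,0.200,pi,342.47,0
Bacillus subtilis,Bs,bacteria,haploid,0.36,0.43,1.20,3.35,0.041,theta,61.19,0
Escherichia coli,Ec,bacteria,haploid,0.39,0.46,0.37,2.00,0.071,theta,179.60,0
Mesoplasma florum,Mf,bacteria,haploid,0.07,0.08,23.10,97.80,0.021,theta,1.07,0
Pseudomonas aeruginosa,Pa,bacteria,haploid,0.59,0.67,0.14,0.79,0.033,pi,210.70,0
Staphylococcus epidermidis,Se,bacteria,haploid,0.21,0.26,1.13,7.40,0.052,theta,35.14,0
Vibrio cholerae,Vc,bacteria,haploid,0.34,0.39,0.18,1.15,0.110,theta,478.26,0
Arabidopsis thaliana,At,multicellular_eukaryote,diploid,4.21,5.55,11.20,69.50,0.008,theta,0.29,0
Caenorhabditis elegans,Ce,multicellular_eukaryote,diploid,2.50,6.37,6.69,14.50,0.003,theta,0.54,0
Chlamydomonas reinhardtii,Cr,unicellular_eukaryote,haploid,3.92,5.51,0.44,3.80,0.032,theta,43.31,0
Drosophila melanogaster,Dm,multicellular_eukaryote,diploid,2.32,8.86,4.61,51.65,0.018,theta,0.86,0
Homo sapiens,Hs,multicellular_eukaryote,diploid,3.65,21.75,18.20,135.13,0.001,theta,0.02,0
Mus musculus,Mm,multicellular_eukaryote,diploid,3.55,27.17,3.10,54.00,0.004,pi,1.77,1
Paramecium tetraurelia,Pt,unicellular_eukaryote,diploid,5.68,7.28,0.04,0.19,0.008,theta,101.80,0
Saccharomyces cerevisiae,Sc,unicellular_eukaryote,haploid,0.87,1.02,0.92,2.63,0.004,theta,7.78,0
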