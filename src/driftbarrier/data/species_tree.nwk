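(((Agt:1,((Ec:1,Vc:1):1,Pa:1):1):1,((Bs:1,Se:1):1,Mf:1):1):1,(((Sc:1,(Dm:1,(Ce:1,(Hs:1,Mm:1):1):1):1):1,(At:1,Cr:1):1):1,Pt:1):1);
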