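pt,hlgt,subgroup,icd_flag
retrograde ejaculation,sexual function and fertility disorders,ejaculatory_dysfunction,0
ejaculation failure,sexual function and fertility disorders,ejaculatory_dysfunction,0
ejaculation disorder,sexual function and fertility disorders,ejaculatory_dysfunction,0
erectile dysfunction,sexual function and fertility disorders,erectile_dysfunction,0
priapism,sexual function and fertility disorders,erectile_dysfunction,0
sexual dysfunction,sexual function and fertility disorders,none,0
anorgasmia,sexual function and fertility disorders,none,0
libido decreased,sexual function and fertility disorders,hyposexuality,0
loss of libido,sexual function and fertility disorders,hyposexuality,0
libido increased,sexual function and fertility disorders,hypersexuality,1
compulsive sexual behavior,"sexual dysfunctions, disturbances and gender identity disorders",hypersexuality,1
hypersexuality,"sexual dysfunctions, disturbances and gender identity disorders",hypersexuality,1
excessive masturbation,"sexual dysfunctions, disturbances and gender identity disorders",hypersexuality,1
psychosexual disorder,"sexual dysfunctions, disturbances and gender identity disorders",none,0
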