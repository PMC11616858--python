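code,qualifier,class,score
H200,,physical,3
H201,,physical,3
H202,,physical,3
H203,,physical,3
H205,,physical,3
H220,,physical,3
H222,,physical,3
H224,,physical,3
H225,,physical,3
H228,category 1,physical,3
H230,,physical,3
H270,,physical,3
H271,,physical,3
H272,category 2,physical,3
H240,,physical,3
H241,,physical,3
H242,type c,physical,3
H242,type d,physical,3
H250,,physical,3
H251,,physical,3
H260,,physical,3
H261,category 2,physical,3
H204,,physical,2
H221,,physical,2
H223,,physical,2
H226,,physical,2
H227,,physical,2
H228,category 2,physical,2
H229,,physical,2
H231,,physical,2
H272,category 3,physical,2
H242,type e,physical,2
H242,type f,physical,2
H252,,physical,2
H261,category 3,physical,2
H280,,physical,2
H281,,physical,2
H290,,physical,2
H300,,health,3
H301,,health,3
H304,,health,3
H310,,health,3
H311,,health,3
H314,,health,3
H318,,health,3
H330,,health,3
H331,,health,3
H334,,health,3
H340,,health,3
H341,,health,3
H350,,health,3
H351,,health,3
H360,,health,3
H361,,health,3
H370,,health,3
H371,,health,3
H372,,health,3
H373,,health,3
H302,,health,2
H305,,health,2
H312,,health,2
H315,,health,2
H317,,health,2
H319,,health,2
H332,,health,2
H335,,health,2
H336,,health,2
H362,,health,2
H400,,environmental,3
H401,,environmental,3
H410,,environmental,3
H411,,environmental,3
H420,,environmental,3
H402,,environmental,2
H412,,environmental,2
H413,,environmental,2
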