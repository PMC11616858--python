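principle,points,criterion
P1,3,Waste is innocuous (S = 1)
P1,2,Waste involves moderate hazard to human health and environment (S = 2)
P1,1,Waste involves high hazard to human health and environment (S = 3)
P2,3,Reactions without excess reagents (<=10%) and no byproducts
P2,2,Reactions without excess reagents (<=10%) and with byproducts
P2,2,Reactions with excess reagents (>10%) and no byproducts
P2,1,Reactions with excess reagents (>10%) and with byproducts
P3,3,All substances involved are innocuous (S = 1)
P3,2,Substances involved have moderate hazard (S = 2)
P3,1,Substances involved have high hazard (S = 3)
P4,3,Designed chemicals are non-toxic to humans and the environment (S = 1)
P4,2,Designed chemicals have moderate toxicity (S = 2)
P4,1,Designed chemicals have high toxicity (S = 3)
P5,3,"No solvents or auxiliary substances, or they are innocuous (S = 1)"
P5,2,Solvents or auxiliary substances have moderate hazard (S = 2)
P5,1,Solvents or auxiliary substances have high hazard (S = 3)
P6,3,Room temperature and pressure
P6,2,Ambient pressure at temperature between 0 and 100 C (cooling/heating required)
P6,1,Different pressure or temperature >100 C or <0 C
P7,3,All raw materials/feedstocks are renewable
P7,2,At least one raw material/feedstock is renewable
P7,1,No raw materials/feedstocks are renewable
P8,3,No derivatizations or similar operations
P8,2,Only one derivatization or similar operation
P8,1,More than one derivatization or similar operation
P9,3,No catalysts or innocuous catalysts (S = 1)
P9,2,Catalysts with moderate hazard (S = 2)
P9,1,Catalysts with high hazard (S = 3)
P10,3,All substances are degradable and break down to innocuous products (S = 1)
P10,2,Not degradable but can be treated to become innocuous products (S = 2)
P10,1,Not degradable and cannot be treated to become innocuous products (S = 3)
P11,3,Continuous monitoring and analysis
P11,2,Periodic monitoring and analysis
P11,1,No real-time monitoring or analysis
P12,3,Substances have low hazard for chemical accidents (S = 1) considering health and physical hazards
P12,2,Substances have moderate hazard for chemical accidents (S = 2)
P12,1,Substances have high hazard for chemical accidents (S = 3)
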