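keyword,category,country
women,gender,all
woman,gender,all
girls,gender,all
boys,gender,all
mothers,gender,all
fathers,gender,all
gender,gender,all
transgender,gender,all
nonbinary,gender,all
lgbtq,gender,all
maternal,gender,all
widows,gender,all
daughters,gender,all
sons,gender,all
grandmothers,gender,all
grandfathers,gender,all
femininity,gender,all
masculinity,gender,all
matriarchs,gender,all
patriarchs,gender,all
children,age,all
child,age,all
elderly,age,all
seniors,age,all
youth,age,all
teenagers,age,all
toddlers,age,all
infants,age,all
adolescents,age,all
retirees,age,all
pensioners,age,all
newborns,age,all
adults,age,all
minors,age,all
youngsters,age,all
octogenarians,age,all
preschoolers,age,all
schoolchildren,age,all
millennials,age,all
boomers,age,all
muslims,culture,all
christians,culture,all
hindus,culture,all
sikhs,culture,all
jews,culture,all
buddhists,culture,all
indigenous,culture,all
francophone,culture,all
anglophone,culture,all
immigrants,culture,all
refugees,culture,all
migrants,culture,all
diaspora,culture,all
multicultural,culture,all
ramadan,culture,all
diwali,culture,all
eid,culture,all
easter,culture,all
hanukkah,culture,all
interfaith,culture,all
latino,ethnicity,all
latina,ethnicity,all
hispanic,ethnicity,all
asian,ethnicity,all
african,ethnicity,all
arab,ethnicity,all
kurdish,ethnicity,all
romani,ethnicity,all
inuit,ethnicity,all
metis,ethnicity,all
maori,ethnicity,all
aboriginal,ethnicity,all
berber,ethnicity,all
pashtun,ethnicity,all
slavic,ethnicity,all
nordic,ethnicity,all
celtic,ethnicity,all
creole,ethnicity,all
mestizo,ethnicity,all
sami,ethnicity,all
nurses,employment,all
doctors,employment,all
teachers,employment,all
farmers,employment,all
workers,employment,all
drivers,employment,all
paramedics,employment,all
firefighters,employment,all
police,employment,all
soldiers,employment,all
fishermen,employment,all
miners,employment,all
engineers,employment,all
cleaners,employment,all
cashiers,employment,all
entrepreneurs,employment,all
caregivers,employment,all
pharmacists,employment,all
veterinarians,employment,all
shopkeepers,employment,all
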