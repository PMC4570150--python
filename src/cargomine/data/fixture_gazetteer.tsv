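# name	tier	country	region	mesh_listed
United States	country	United States		1
USA	country	United States
United States of America	country	United States
Italy	country	Italy		1
China	country	China		1
PRC	country	China
United Kingdom	country	United Kingdom		1
UK	country	United Kingdom
Great Britain	country	United Kingdom
France	country	France		1
Germany	country	Germany		1
Japan	country	Japan		1
Brazil	country	Brazil		1
Russia	country	Russia		1
Serbia	country	Serbia		1
Croatia	country	Croatia		1
Andorra	country	Andorra		1
Kosovo	country	Kosovo
Republic of Kosovo	country	Kosovo
Yugoslavia	historical_country	Serbia;Croatia
USSR	historical_country	Russia
Soviet Union	historical_country	Russia
Pacific Ocean	water_body
Atlantic Ocean	water_body
Coral Sea	water_body
Massachusetts	admin1	United States	Massachusetts
New York	admin1	United States	New York
California	admin1	United States	California
MA	state_code	United States	Massachusetts
NY	state_code	United States	New York
CA	state_code	United States	California
Boston	city	United States	Massachusetts
Los Angeles	city	United States	California
Regione Lombardia	admin1	Italy	Regione Lombardia
Lombardia	admin1	Italy	Regione Lombardia
Lazio	admin1	Italy	Lazio
Milan	city	Italy	Regione Lombardia
Milano	city	Italy	Regione Lombardia
Rome	capital	Italy	Lazio
Quangdong sheng	admin1	China	Quangdong sheng
Guangdong	admin1	China	Quangdong sheng
Beijing	admin1	China	Beijing
Shantou	city	China	Quangdong sheng
Guangzhou	city	China	Quangdong sheng
England	admin1	United Kingdom	England
Scotland	admin1	United Kingdom	Scotland
Wales	admin1	United Kingdom	Wales
Yorkshire	admin2	United Kingdom	England
Old Peak	village	United Kingdom	England
London	capital	United Kingdom	England
Glasgow	city	United Kingdom	Scotland
Edinburgh	city	United Kingdom	Scotland
Ile-de-France	admin1	France	Ile-de-France
Provence-Alpes-Cote d'Azur	admin1	France	Provence-Alpes-Cote d'Azur
Paris	capital	France	Ile-de-France
Marseille	city	France	Provence-Alpes-Cote d'Azur
Bavaria	admin1	Germany	Bavaria
Bayern	admin1	Germany	Bavaria
Munich	city	Germany	Bavaria
Tokyo	admin1	Japan	Tokyo
Hokkaido	admin1	Japan	Hokkaido
Sapporo	city	Japan	Hokkaido
Sao Paulo	admin1	Brazil	Sao Paulo
Rio de Janeiro	admin1	Brazil	Rio de Janeiro
Moskva	admin1	Russia	Moskva
Moscow	capital	Russia	Moskva
Central Serbia	admin1	Serbia	Central Serbia
Belgrade	capital	Serbia	Central Serbia
City of Zagreb	admin1	Croatia	City of Zagreb
Zagreb	capital	Croatia	City of Zagreb
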